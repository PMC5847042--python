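import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ihc4c import scores as sc
from ihc4c import survival as sv
from ihc4c.synthetic import GeneratorConfig, generate_cohort

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One default 430-patient synthetic cohort (seed 1)."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def scored_default(default_cohort):
    """The default cohort after eligibility filtering, scoring and TTDR derivation."""
    kept, exclusions = sc.eligibility_filter(default_cohort.cohort)
    scored = sv.derive_ttdr_frame(sc.score_cohort(kept))
    return scored, exclusions


def random_marker_panel(rng: np.random.Generator) -> sc.MarkerPanel:
    return sc.MarkerPanel(
        er_hscore=float(rng.uniform(0, 300)),
        pgr_percent=float(rng.uniform(0, 100)),
        her2_ihc=rng.choice(["0", "1+", "2+", "3+"]),
        ki67_percent=float(rng.uniform(0, 100)),
    )


def random_clinical_profile(rng: np.random.Generator) -> sc.ClinicalProfile:
    return sc.ClinicalProfile(
        age_years=float(rng.uniform(40, 90)),
        nodal_category=sc.NodalCategory(rng.choice(["N0", "N1to3", "Ngt3"])),
        tumour_size_cm=float(rng.uniform(0.2, 8.0)),
        grade=sc.Grade(rng.choice(["G1", "G2", "G3"])),
        treatment=sc.Treatment(rng.choice(["tamoxifen_only", "switch_to_exemestane"])),
    )
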