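import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ctlkit.io import DomainHit, Taxonomy
from ctlkit.simulate import ExperimentSpec, ExpressionSpec, ScenarioConfig, generate_scenario

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("default")


def make_hit(protein_id="p1", accession="PF00059.21", start=10, end=120, **kw):
    return DomainHit(
        protein_id=protein_id,
        pfam_accession=accession,
        pfam_id=kw.get("pfam_id", "Lectin_C"),
        env_start=start,
        env_end=end,
        bitscore=kw.get("bitscore", 50.0),
        evalue=kw.get("evalue", 1e-10),
    )


@pytest.fixture
def toy_taxonomy8():
    """One phylum, two classes of two 2-species families each."""
    rows = []
    for cls, fams in (("c1", ("f1", "f2")), ("c2", ("f3", "f4"))):
        for fam in fams:
            for i in (1, 2):
                rows.append(
                    {
                        "species_id": f"{fam}s{i}",
                        "family": fam,
                        "class": cls,
                        "phylum": "p1",
                    }
                )
    return Taxonomy(pd.DataFrame(rows))


def tiny_config(seed=0, **overrides):
    """A fast, structurally complete scenario for property tests."""
    base = dict(
        taxonomy={
            "Mollusca": {
                "Bivalvia": {"Myt": 3, "Ost": 3, "Pec": 3},
                "Cephalopoda": {"Oct": 3, "Sep": 3, "Arc": 3},
            },
            "Chordata": {"Mammalia": {"Hom": 2}},
        },
        n_phylum_conserved=2,
        n_class_conserved=2,
        n_multi_family=2,
        n_family_specific=2,
        n_restricted=3,
        n_ctldcp_a=2,
        n_ctldcp_b=2,
        n_ctldcp_c=2,
        n_background_genes=5,
        expression=ExpressionSpec(
            n_baseline_per_type=2,
            n_hemocyte_program=3,
            experiments=[
                ExperimentSpec(
                    "toxin_dg", "digestive_gland", "mucosal",
                    n_control=3, n_stimulated=3,
                )
            ],
        ),
        seed=seed,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size scenario shared across test modules (noise-free)."""
    return generate_scenario(ScenarioConfig(seed=42))


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_scenario(tiny_config(seed=11))
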