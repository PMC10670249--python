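import pytest

from ringcyto.synthetic_cohort import GeneratorConfig, generate_cohort

# The four published non-complex ring-chromosome karyotypes (printed with a
# Unicode minus and an internal space, as in the source text).
NONCOMPLEX_KARYOTYPES = [
    "46,XY,−7,+r",
    "46,XY,−18,+r",
    "48,XX,+4,+r",
    "46,XX,r(18)(p11.3q23)[2]/46,XX,t(7;17) (q36;q21)[2]/46,XX[15]",
]


@pytest.fixture(scope="session")
def noncomplex_karyotypes():
    return list(NONCOMPLEX_KARYOTYPES)


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient synthetic cohort with its truth ledger (fixed seed)."""
    cfg = GeneratorConfig(n_patients=120, seed=42)
    records, ledger = generate_cohort(cfg)
    return cfg, records, ledger
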