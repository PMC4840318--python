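import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ablineage import Rearrangement, SimConfig, simulate_repertoire


def make_rec(
    sequence_id="r1",
    v_gene="IGHV3-23*01",
    j_gene="IGHJ4*01",
    cdr3_aa="CARDYW",
    junction_nt=None,
    mutations=(),
    donor_id=None,
):
    """Minimal scorable rearrangement for metric/cluster tests."""
    if junction_nt is None:
        from ablineage.simulate import _AA_TO_CODON

        body = "".join(_AA_TO_CODON.get(aa, "GCA") for aa in cdr3_aa)
        junction_nt = "TGT" + body + "TGG"
    return Rearrangement(
        sequence_id=sequence_id,
        v_gene=v_gene,
        j_gene=j_gene,
        junction_nt=junction_nt,
        cdr3_aa=cdr3_aa,
        mutations=list(mutations),
        donor_id=donor_id,
    )


@pytest.fixture(scope="session")
def default_repertoire():
    """A default-condition simulated repertoire (50 lineages, star SHM)."""
    return simulate_repertoire(SimConfig(seed=3))


@pytest.fixture(scope="session")
def recovery_repertoire():
    """A 50-lineage repertoire with larger clones (~600 sequences), used for
    parameter-recovery checks."""
    cfg = SimConfig(seed=42, n_lineages=50, alpha=1.3, max_lineage_size=100)
    return simulate_repertoire(cfg)
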