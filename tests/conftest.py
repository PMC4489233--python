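import pytest
from hypothesis import HealthCheck, settings

from topoconsensus import SimConfig, TopologyString
from topoconsensus.evaluation import ErrorKind
from topoconsensus.simulate import simulate_dataset

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

_H = "M" * 21

# Hand-built evaluation pairs: (id, reference, prediction, expected kind).
# Pairs 2/3 sit on the overlap boundary (5 shared residues is correct,
# 4 is not); every error kind of the taxonomy appears at least once.
_REF1 = "i" * 10 + _H + "o" * 30                       # TM, helix [10, 31)
_REF_SPTM = "S" * 20 + "o" * 10 + _H + "i" * 10        # SP+TM
EVAL_FIXTURE = [
    ("ex01", _REF1, _REF1, ErrorKind.CORRECT),
    ("ex02", _REF1, "i" * 26 + _H + "o" * 14, ErrorKind.CORRECT),          # overlap 5
    ("ex03", _REF1, "i" * 27 + _H + "o" * 13, ErrorKind.WRONG_TOPOLOGY),   # overlap 4
    (
        "ex04",  # extra predicted helix
        "i" * 5 + _H + "o" * 10 + _H + "i" * 13,
        "i" * 5 + _H + "o" * 10 + _H + "i" * 3 + "M" * 7 + "o" * 3,
        ErrorKind.WRONG_TOPOLOGY,
    ),
    ("ex05", _REF1, "o" * 10 + _H + "i" * 30, ErrorKind.WRONG_TOPOLOGY),   # inverted
    ("ex06", _REF_SPTM, _REF_SPTM, ErrorKind.CORRECT),
    (
        "ex07",  # SP read as N-terminal helix
        _REF_SPTM,
        "M" * 20 + "o" * 10 + _H + "i" * 10,
        ErrorKind.TM_SP_CONFUSION,
    ),
    ("ex08", _REF1, "S" * 31 + "o" * 30, ErrorKind.TM_SP_CONFUSION),       # helix read as SP
    ("ex09", "i" * 50, "i" * 50, ErrorKind.CORRECT),
    ("ex10", "o" * 60, "o" * 20 + _H + "i" * 19, ErrorKind.TM_NONTM_CONFUSION),
    ("ex11", "S" * 20 + "o" * 40, "o" * 60, ErrorKind.SP_NONTM_CONFUSION), # missed SP
    ("ex12", _REF1, "i" * 61, ErrorKind.TM_NONTM_CONFUSION),               # missed protein
]

EXPECTED_TALLY = {
    ErrorKind.CORRECT: 4,
    ErrorKind.WRONG_TOPOLOGY: 3,
    ErrorKind.TM_SP_CONFUSION: 2,
    ErrorKind.TM_NONTM_CONFUSION: 2,
    ErrorKind.SP_NONTM_CONFUSION: 1,
}


@pytest.fixture(scope="session")
def eval_fixture():
    return [
        (TopologyString(pid, ref), TopologyString(pid, pred), kind)
        for pid, ref, pred, kind in EVAL_FIXTURE
    ]


@pytest.fixture(scope="session")
def default_ensemble():
    """500 synthetic proteins with 5 noisy methods each, fixed seed."""
    cfg = SimConfig(seed=11, n_proteins=500)
    return cfg, simulate_dataset(cfg)
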