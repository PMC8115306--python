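import pathlib

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from isomirkit import ArmAligner, build_reference, default_config, simulate_reads


@pytest.fixture(scope="session")
def ref10():
    return build_reference(10, seed=11)


@pytest.fixture(scope="session")
def aligner10(ref10):
    return ArmAligner(ref10)


@pytest.fixture(scope="session")
def small_sim(ref10, tmp_path_factory):
    """Error-free 4-sample simulation at moderate depth, shared read-only."""
    cfg = default_config(
        ref10,
        depth=3000,
        seed=5,
        error_rate=0.0,
        group_design={
            "BN_1": "nevus", "BN_2": "nevus",
            "CM_1": "single", "CM_2": "single",
        },
        pairing={},
    )
    out = tmp_path_factory.mktemp("small_sim")
    return simulate_reads(ref10, cfg, out)


def truth_labels(truth_df):
    """Render truth-table rows as isomiR label strings."""
    from isomirkit import IsomirLabel

    return truth_df.apply(
        lambda r: IsomirLabel(
            r.mirna_name, int(r.d5), int(r.d3), (r.nta or "") if isinstance(r.nta, str) else ""
        ).render(),
        axis=1,
    )


@pytest.fixture(scope="session")
def repo_root():
    return pathlib.Path(__file__).resolve().parents[1]
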