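import numpy as np
import pytest

from grainfluor import RunConfig, run_pipeline
from grainfluor.synthetic import (
    STAGES,
    GeometryParams,
    generate_phantom,
)

#: Small working grid for unit tests; same physical field of view as
#: the default grid, coarser pixels.
SMALL_GEOM = GeometryParams(shape=(192, 256))


@pytest.fixture(scope="session")
def small_phantoms():
    """One phantom per developmental stage on the small grid."""
    return {s: generate_phantom(s, SMALL_GEOM, seed=100 + s) for s in STAGES}


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A complete small pipeline run: 4 stages x 2 sections, 192x256."""
    out = tmp_path_factory.mktemp("small_run")
    cfg = RunConfig(
        out_dir=str(out / "run"),
        design={s: 2 for s in STAGES},
        shape=(192, 256),
        seed=11,
        write_score_tiffs=False,
    )
    summary = run_pipeline(cfg)
    return cfg, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
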