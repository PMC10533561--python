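import pandas as pd
import pytest

from hybseq import report, simulate
from hybseq.config import AssayConfig
from hybseq.readproc import SampleSheet


@pytest.fixture(scope="session")
def cfg():
    return AssayConfig()


@pytest.fixture(scope="session")
def clones(cfg):
    return simulate.make_reference_set(4, seed=11, config=cfg)


@pytest.fixture(scope="session")
def mini_run(cfg, clones, tmp_path_factory):
    """Error-free 12-well plate run end to end once per session."""
    tmp = tmp_path_factory.mktemp("mini")
    spec = simulate.design_plate(
        clones, seed=11, n_subclones=2, n_technical=1,
        depth=50, error_rate=0.0, aberrant_fraction=0.3)
    paths = simulate.simulate_plate(spec, tmp / "plate", cfg)
    sheet = SampleSheet(simulate.sample_sheet(spec))
    db, census, counts = report.run_pipeline(
        cfg, paths["r1"], paths["r2"], sheet, tmp / "out")
    truth = pd.read_csv(paths["truth"], sep="\t")
    return {
        "spec": spec, "paths": paths, "sheet": sheet, "db": db,
        "census": census, "counts": counts, "truth": truth, "dir": tmp,
    }
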