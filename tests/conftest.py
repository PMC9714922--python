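import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from softhier import PipelineConfig, SyntheticConfig, generate_cluster, run_pipeline


@pytest.fixture(scope="session")
def fixture_cluster(tmp_path_factory):
    """One deterministic 3-node path cluster plus its pipeline outputs."""
    root = tmp_path_factory.mktemp("fixture_cluster")
    cfg = SyntheticConfig(seed=42, overlap_f=0.8)
    paths, truth = generate_cluster(cfg, root / "fix")
    pcfg = PipelineConfig(manifest=root / "fix" / "manifest.tsv",
                          outdir=root / "out", seed=7)
    result = run_pipeline(pcfg)
    return {"config": cfg, "paths": paths, "truth": truth,
            "pipeline_config": pcfg, "result": result,
            "fixture_dir": root / "fix", "outdir": root / "out"}
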