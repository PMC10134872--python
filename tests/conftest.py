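import numpy as np
import pytest

from viamet import RunConfig, generate_study, run_pipeline, write_study
from viamet.qpcr import StandardCurve

#: Slope of a perfect-doubling assay: one decade every log2(10) cycles.
DOUBLING_SLOPE = -1.0 / np.log10(2.0)


@pytest.fixture(scope="session")
def doubling_curve() -> StandardCurve:
    return StandardCurve(slope=DOUBLING_SLOPE, intercept=37.0)


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (3 hosts x 3 groups x 3 reps x 2 types)."""
    return generate_study(seed=11)


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory):
    d = tmp_path_factory.mktemp("study")
    write_study(study, d)
    return d


@pytest.fixture(scope="session")
def report(study_dir, tmp_path_factory):
    """Full pipeline run over the session study; returns (summary, outdir)."""
    out = tmp_path_factory.mktemp("report")
    summary = run_pipeline(
        RunConfig(input_dir=str(study_dir), output_dir=str(out), seed=11,
                  permutations=199)
    )
    return summary, out
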