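"""Shared fixtures: one default synthetic bundle and one full pipeline run."""

import pytest

from ahnet.pipeline_cli import PipelineConfig, run_pipeline
from ahnet.synthetic_data import SyntheticConfig, generate_bundle, write_bundle

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle (study conditions, fixed seed)."""
    return generate_bundle(SyntheticConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    """The default bundle written out as TSV files."""
    outdir = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, outdir)
    return outdir


@pytest.fixture(scope="session")
def pipeline_run(bundle_dir, tmp_path_factory):
    """One full pipeline run on the default bundle: (report, outdir)."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig(
        drugs=str(bundle_dir / "drugs.tsv"),
        interactions=str(bundle_dir / "interactions.tsv"),
        go_annotations=str(bundle_dir / "go_annotations.tsv"),
        associations=str(bundle_dir / "associations.tsv"),
        combination_pairs=str(bundle_dir / "combinations.tsv"),
        name_map=str(bundle_dir / "name_map.tsv"),
        outdir=str(outdir),
    )
    report = run_pipeline(config)
    return report, outdir
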