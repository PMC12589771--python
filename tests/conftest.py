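import warnings

import pytest

import histoexpr as hx

warnings.filterwarnings("ignore", category=UserWarning, module="scanpy")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_sim():
    """One modest slide shared by read-only tests: 50 cells, 30 genes."""
    cfg = hx.SynthConfig(n_cells=50, n_genes=30, seed=7, image_size_px=(640, 640))
    image, polygons, bins, truth = hx.simulate_slide(cfg)
    return cfg, image, polygons, bins, truth


@pytest.fixture(scope="session")
def fixture_dir(small_sim, tmp_path_factory):
    cfg, image, polygons, bins, truth = small_sim
    directory = tmp_path_factory.mktemp("fixture")
    paths = hx.write_fixture((image, polygons, bins, truth), directory)
    return directory, paths
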