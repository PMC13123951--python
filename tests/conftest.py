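import os

# pin BLAS threads before numpy loads: the training loop is memory-bound at
# desk scale and thread thrash on small matmuls slows it down
for var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(var, "1")

import numpy as np
import pytest

from usgan.images import load_image
from usgan.metrics import ROIPair
from usgan.phantom import generate_dataset
from usgan.train import SwitchableCycleGAN, TrainConfig


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """8+8 unpaired synthetic 64x64 images with ground-truth masks."""
    root = tmp_path_factory.mktemp("phantom64")
    generate_dataset(8, root, seed=11, height=64, width=64)
    x_paths = sorted((root / "X").glob("*.png"))
    y_paths = sorted((root / "Y").glob("*.png"))
    xs = [load_image(p).values for p in x_paths]
    ys = [load_image(p).values for p in y_paths]
    rois = []
    for p in x_paths:
        fg = load_image(root / "masks" / f"X_{p.stem}_fg.png").values > 0.5
        bg = load_image(root / "masks" / f"X_{p.stem}_bg.png").values > 0.5
        rois.append(ROIPair(fg, bg))
    return {"root": root, "xs": xs, "ys": ys, "rois": rois}


@pytest.fixture(scope="session")
def desk_run(phantom_dataset):
    """One seeded 200-step desk-scale training run, shared across tests."""
    cfg = TrainConfig(crop_size=64, resize_to=64, seed=5, epochs=1,
                      steps_per_epoch=200)
    model = SwitchableCycleGAN(phantom_dataset["xs"], phantom_dataset["ys"],
                               cfg, base_channels=16, n_res_blocks=3)
    return model.fit()
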