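"""Synthetic atlas-grouped activation data with known ground truth.

Emulates the statistical structure of group-level fMRI contrast features
in a case/control design: a toy 3-D volume is partitioned into cuboid
pseudo-atlas areas; a subset of areas carries a class effect (patients
minus controls); spatially smooth Gaussian noise is added; each patient's
activation pattern is translated by a small random integer jitter
(inter-subject variability, the regime where voxel-wise sparsity is
fragile and group-wise sparsity is expected to be robust); and a fraction
of entries is replaced by |Z| > 5 outliers, which the preprocessing
outlier filter is meant to remove.

Everything is deterministic given the spec's seed, and the generator
returns the ground-truth support so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from itertools import product
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import FeatureMatrix, assemble, concat_tasks, save_nifti_volume

#: Injected outliers are drawn uniformly from +/-[OUTLIER_LO, OUTLIER_HI],
#: safely above the |Z| > 5 filter threshold.
OUTLIER_LO = 5.5
OUTLIER_HI = 8.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    grid_shape : 3-D extents of the toy brain volume (voxels)
    n_areas : number of cuboid pseudo-atlas areas
    n_per_class : subjects per label (controls = patients)
    active_areas : 1-based area labels carrying the class effect
    effect_size : mean Z-score difference, patients minus controls, in
        active voxels (dimensionless)
    smooth_sigma : Gaussian correlation length of the noise field, voxels
        (0 disables smoothing)
    jitter_max : max per-subject integer translation of the activation
        pattern along each axis, voxels (circular shift)
    noise_sd : marginal SD of the additive noise field, Z units
    outlier_rate : fraction of matrix entries replaced by |Z| > 5 values
    seed : RNG seed
    """

    grid_shape: tuple[int, int, int] = (12, 12, 6)
    n_areas: int = 24
    n_per_class: int = 20
    active_areas: tuple[int, ...] = (1, 2, 3)
    effect_size: float = 1.5
    smooth_sigma: float = 1.0
    jitter_max: int = 1
    noise_sd: float = 1.0
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.n_areas < 1 or self.n_areas > int(np.prod(self.grid_shape)):
            raise ValueError("n_areas must be in [1, number of voxels]")
        if not set(self.active_areas) <= set(range(1, self.n_areas + 1)):
            raise ValueError("active_areas must be a subset of {1..n_areas}")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must lie in [0, 1]")
        if self.jitter_max < 0:
            raise ValueError("jitter_max must be >= 0")
        if self.noise_sd < 0 or self.smooth_sigma < 0:
            raise ValueError("noise_sd and smooth_sigma must be >= 0")


@dataclass
class SyntheticDataset:
    """A generated dataset with its atlas and ground truth."""

    features: FeatureMatrix
    atlas: np.ndarray
    truth_voxels: np.ndarray  # column positions of truly discriminative voxels
    truth_areas: tuple[int, ...]  # 1-based atlas labels (== spec.active_areas)
    spec: SyntheticSpec


def _factor_triple(n_areas: int, grid_shape) -> tuple[int, int, int]:
    """Factor n_areas into axis counts (a, b, c) fitting the grid.

    Among all factorizations with a <= nx, b <= ny, c <= nz, pick the one
    whose per-area blocks are closest to cubes (minimal spread of block
    edge lengths in log scale).
    """
    nx, ny, nz = grid_shape
    best = None
    for a in range(1, n_areas + 1):
        if n_areas % a:
            continue
        rest = n_areas // a
        for b in range(1, rest + 1):
            if rest % b:
                continue
            c = rest // b
            if a > nx or b > ny or c > nz:
                continue
            edges = np.log([nx / a, ny / b, nz / c])
            cost = float(np.ptp(edges))
            if best is None or cost < best[0]:
                best = (cost, (a, b, c))
    if best is None:
        raise ValueError(
            f"cannot partition grid {tuple(grid_shape)} into {n_areas} cuboid areas"
        )
    return best[1]


def make_atlas(spec: SyntheticSpec) -> np.ndarray:
    """Partition the volume into n_areas contiguous cuboids labeled 1..n_areas.

    Axes are split into nearly equal slabs; every voxel receives exactly
    one label.
    """
    parts = _factor_triple(spec.n_areas, spec.grid_shape)
    bounds = [
        np.linspace(0, extent, n + 1).round().astype(int)
        for extent, n in zip(spec.grid_shape, parts)
    ]
    atlas = np.zeros(spec.grid_shape, dtype=np.int32)
    label = 1
    for ia, ib, ic in product(*(range(n) for n in parts)):
        atlas[
            bounds[0][ia] : bounds[0][ia + 1],
            bounds[1][ib] : bounds[1][ib + 1],
            bounds[2][ic] : bounds[2][ic + 1],
        ] = label
        label += 1
    return atlas


def _noise_field(rng: np.random.Generator, shape, sigma: float, sd: float) -> np.ndarray:
    """Spatially smooth Gaussian field with marginal SD ``sd``."""
    white = rng.standard_normal(shape)
    if sigma == 0 or sd == 0:
        return sd * white
    smooth = gaussian_filter(white, sigma=sigma, mode="wrap")
    # rescale so the marginal SD is sd again (smoothing shrinks variance by
    # the kernel's L2 norm; computed from the kernel itself)
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = gaussian_filter(impulse, sigma=sigma, mode="wrap")
    scale = np.sqrt(np.sum(kernel**2))
    return sd * smooth / scale


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a labeled synthetic dataset (controls first, then patients).

    Patient rows add ``effect_size`` to the active-area voxels after a
    per-subject integer circular shift drawn uniformly from
    [-jitter_max, +jitter_max]^3; all rows receive a smoothed noise field;
    ``outlier_rate`` of the entries are then replaced by values of
    magnitude in [5.5, 8] with random sign.  Bit-identical given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    atlas = make_atlas(spec)
    active_mask = np.isin(atlas, spec.active_areas).astype(float)

    n = 2 * spec.n_per_class
    volumes = []
    for subj in range(n):
        vol = _noise_field(rng, spec.grid_shape, spec.smooth_sigma, spec.noise_sd)
        is_patient = subj >= spec.n_per_class
        if spec.jitter_max > 0:
            shift = rng.integers(-spec.jitter_max, spec.jitter_max + 1, size=3)
        else:
            shift = np.zeros(3, dtype=int)
        if is_patient and spec.effect_size != 0:
            mask = np.roll(active_mask, shift, axis=(0, 1, 2))
            vol = vol + spec.effect_size * mask
        volumes.append(vol)

    labels = np.concatenate(
        [-np.ones(spec.n_per_class, dtype=int), np.ones(spec.n_per_class, dtype=int)]
    )
    subject_ids = [f"ctrl{i:03d}" for i in range(spec.n_per_class)] + [
        f"pat{i:03d}" for i in range(spec.n_per_class)
    ]
    fm = assemble(volumes, atlas, labels, subject_ids=subject_ids, task="synthetic-A")

    if spec.outlier_rate > 0:
        n_entries = fm.values.size
        n_out = int(round(spec.outlier_rate * n_entries))
        flat = rng.choice(n_entries, size=n_out, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        mags = rng.uniform(OUTLIER_LO, OUTLIER_HI, size=n_out)
        fm.values.flat[flat] = signs * mags

    truth_voxels = np.flatnonzero(np.isin(fm.voxel_index["area"].to_numpy(), spec.active_areas))
    return SyntheticDataset(fm, atlas, truth_voxels, tuple(spec.active_areas), spec)


def generate_combined(spec: SyntheticSpec, seed_b: int | None = None):
    """Two-task mode: two independent datasets with shared labels, concatenated.

    Mirrors combining two task feature matrices by simple concatenation,
    with the second task's areas forming distinct groups.  Returns
    (FeatureMatrix, GroupStructure, dataset_a, dataset_b).
    """
    ds_a = generate(spec)
    spec_b = replace(spec, seed=spec.seed + 1 if seed_b is None else seed_b)
    ds_b = generate(spec_b)
    fm_b = ds_b.features
    fm_b.voxel_index = fm_b.voxel_index.assign(task="synthetic-B")
    combined, groups = concat_tasks(ds_a.features, fm_b)
    return combined, groups, ds_a, ds_b


def save_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write atlas (NIfTI int), features (TSV + sidecar), truth (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_nifti_volume(ds.atlas, out / "atlas.nii.gz", integer=True)
    ds.features.to_tsv(out / "features.tsv")
    truth = {
        "truth_voxels": ds.truth_voxels.tolist(),
        "truth_areas": list(ds.truth_areas),
        "spec": asdict(ds.spec),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
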