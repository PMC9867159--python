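"""Synthetic thermogram subjects and tabular benchmarks with known ground truth.

Real plantar-thermogram cohorts are not redistributable, so every downstream
stage of the pipeline is exercised on generated data instead:

* foot-shaped temperature maps whose per-class foot means follow the
  distributions reported for diabetic (30.2 ± 1.3 °C) and healthy
  (26.8 ± 1.8 °C) feet, with localized hot spots on diabetic feet only, and
* plain two-class feature tables with a known informative-feature subset,
  for benchmarking the feature selectors at a chosen signal strength.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

# ---------------------------------------------------------------------------
# constants

#: integer labels used in angiosome mask grids
BACKGROUND, MPA, LPA, MCA, LCA = 0, 1, 2, 3, 4
ANGIOSOME_NAMES = ("MPA", "LPA", "MCA", "LCA")
ANGIOSOME_LABELS = {"MPA": MPA, "LPA": LPA, "MCA": MCA, "LCA": LCA}

#: reported foot-mean temperature distributions (°C) per class
DIABETIC_MEAN, DIABETIC_SD = 30.2, 1.3
HEALTHY_MEAN, HEALTHY_SD = 26.8, 1.8

#: all emitted temperatures are clipped into this half-open range (°C)
TEMP_LO, TEMP_HI = 18.0, 37.0

#: default within-foot smooth texture amplitude (°C, 1 SD)
TEXTURE_SD = 0.8

HEALTHY, DIABETIC = "healthy", "diabetic"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FootGeometry:
    """Rectangular grid holding one elliptical foot silhouette.

    The plantar/calcaneal horizontal cut sits at ``plantar_cut`` (default
    60 %) of the foot height measured from the toes; the medial/lateral
    vertical cut at ``medial_cut`` of the foot width.
    """

    height_px: int = 100
    width_px: int = 60
    plantar_cut: float = 0.6
    medial_cut: float = 0.5

    def __post_init__(self):
        if self.height_px < 4 or self.width_px < 4:
            raise ValueError("foot grid must be at least 4x4 pixels")
        if not (0.0 < self.plantar_cut < 1.0 and 0.0 < self.medial_cut < 1.0):
            raise ValueError("cut fractions must lie strictly in (0, 1)")


@dataclass
class TemperatureMap:
    """One foot: a 2-D grid of temperatures (°C) plus a valid-pixel mask."""

    grid: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.grid.shape != self.valid_mask.shape:
            raise ValueError("grid and valid_mask shapes differ")
        if not self.valid_mask.any():
            raise ValueError("valid_mask selects no pixels")
        if not np.isfinite(self.grid[self.valid_mask]).all():
            raise ValueError("non-finite temperature inside the valid mask")

    @property
    def foot_values(self) -> np.ndarray:
        return self.grid[self.valid_mask]


@dataclass
class SubjectRecord:
    """Both feet of one subject plus the binary class label."""

    subject_id: str
    label: str  # "healthy" | "diabetic"
    left: TemperatureMap
    left_mask: np.ndarray
    right: TemperatureMap
    right_mask: np.ndarray
    seed: int | None = None

    def foot(self, side: str) -> tuple[TemperatureMap, np.ndarray]:
        if side == "L":
            return self.left, self.left_mask
        if side == "R":
            return self.right, self.right_mask
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")


@dataclass(frozen=True)
class TabularSpec:
    """Recipe for a two-class tabular benchmark with known informative columns."""

    n_per_class: int = 200
    n_features: int = 100
    n_informative: int = 10
    effect_size: float = 2.0  # standardized mean shift (Cohen's d)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must not exceed n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


# ---------------------------------------------------------------------------
# angiosome masks


def make_foot_mask(geometry: FootGeometry, side: str) -> np.ndarray:
    """Build an angiosome label grid for one foot.

    The silhouette is an ellipse inscribed in the grid (toes at row 0).
    Rows above the plantar cut carry MPA/LPA, rows below carry MCA/LCA.
    The medial side is the big-toe side: image-right for a left foot,
    image-left for a right foot, so left/right masks mirror each other.
    """
    if side not in ("L", "R"):
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    h, w = geometry.height_px, geometry.width_px
    rows, cols = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    inside = ((rows - cy) / (h / 2.0)) ** 2 + ((cols - cx) / (w / 2.0)) ** 2 <= 1.0
    if not inside.any():
        raise ValueError("degenerate geometry: empty silhouette")

    foot_rows = np.where(inside.any(axis=1))[0]
    foot_cols = np.where(inside.any(axis=0))[0]
    # horizontal cut at plantar_cut of the foot height, from the toes
    cut_row = foot_rows[0] + geometry.plantar_cut * len(foot_rows)
    cut_col = foot_cols[0] + geometry.medial_cut * len(foot_cols)

    plantar = rows < cut_row
    # medial = high column index on a left foot, low on a right foot
    medial = cols >= cut_col if side == "L" else cols < cut_col

    mask = np.zeros((h, w), dtype=np.int64)
    mask[inside & plantar & medial] = MPA
    mask[inside & plantar & ~medial] = LPA
    mask[inside & ~plantar & medial] = MCA
    mask[inside & ~plantar & ~medial] = LCA

    for name, lab in ANGIOSOME_LABELS.items():
        if not (mask == lab).any():
            raise ValueError(
                f"degenerate geometry {h}x{w}: angiosome {name} would be empty; "
                "increase the grid size"
            )
    return mask


# ---------------------------------------------------------------------------
# thermogram subjects


def _smooth_field(shape: tuple[int, int], sd: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean low-frequency random field with pointwise SD ≈ sd."""
    noise = rng.standard_normal(shape)
    sigma = max(min(shape) / 8.0, 1.0)
    sm = gaussian_filter(noise, sigma=sigma, mode="reflect")
    s = sm.std()
    if s < 1e-12:  # pathological tiny grids
        return np.zeros(shape)
    return sm * (sd / s)


def _fill_foot(
    mean_temp: float,
    mask: np.ndarray,
    rng: np.random.Generator,
    texture_sd: float,
    n_hot_spots: int,
    hot_spot_delta: tuple[float, float] = (1.5, 3.0),
) -> TemperatureMap:
    valid = mask != BACKGROUND
    field = _smooth_field(mask.shape, texture_sd, rng)
    field -= field[valid].mean()  # foot mean equals the drawn mean exactly
    grid = mean_temp + field

    ys, xs = np.nonzero(valid)
    for _ in range(n_hot_spots):
        i = rng.integers(len(ys))
        cy, cx = ys[i], xs[i]
        delta = rng.uniform(*hot_spot_delta)
        sigma = rng.uniform(2.0, max(mask.shape[0] / 10.0, 3.0))
        rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        grid = grid + delta * np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * sigma**2))

    grid = np.clip(grid, TEMP_LO, np.nextafter(TEMP_HI, TEMP_LO))
    grid = np.where(valid, grid, np.nan)
    return TemperatureMap(grid=grid, valid_mask=valid)


def make_subject(
    class_label: str,
    geometry: FootGeometry = FootGeometry(),
    seed: int = 0,
    subject_id: str | None = None,
    texture_sd: float = TEXTURE_SD,
    max_hot_spots: int = 3,
) -> SubjectRecord:
    """Generate one subject: both feet, smooth temperature fields, class label.

    The per-subject foot-mean temperature is drawn from the class's normal
    law; diabetic feet additionally receive 0–``max_hot_spots`` localized
    hot-spot blobs of +1.5 to +3 °C each. All temperatures are clipped into
    [18, 37) °C.
    """
    if class_label not in (HEALTHY, DIABETIC):
        raise ValueError(f"class_label must be 'healthy' or 'diabetic', got {class_label!r}")
    rng = np.random.default_rng(seed)
    mu, sd = (DIABETIC_MEAN, DIABETIC_SD) if class_label == DIABETIC else (HEALTHY_MEAN, HEALTHY_SD)
    mean_temp = rng.normal(mu, sd)

    feet = {}
    for side in ("L", "R"):
        mask = make_foot_mask(geometry, side)
        n_spots = int(rng.integers(0, max_hot_spots + 1)) if class_label == DIABETIC else 0
        feet[side] = (_fill_foot(mean_temp, mask, rng, texture_sd, n_spots), mask)

    return SubjectRecord(
        subject_id=subject_id or f"{class_label}_{seed}",
        label=class_label,
        left=feet["L"][0],
        left_mask=feet["L"][1],
        right=feet["R"][0],
        right_mask=feet["R"][1],
        seed=seed,
    )


def make_cohort(
    n_healthy: int,
    n_diabetic: int,
    geometry: FootGeometry = FootGeometry(),
    seed: int = 0,
    **kwargs,
) -> list[SubjectRecord]:
    """Generate a cohort; subject seeds are fanned out from the root seed."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_healthy + n_diabetic)]
    subjects = []
    for i in range(n_healthy):
        subjects.append(make_subject(HEALTHY, geometry, seeds[i], subject_id=f"H{i:04d}", **kwargs))
    for i in range(n_diabetic):
        subjects.append(
            make_subject(DIABETIC, geometry, seeds[n_healthy + i], subject_id=f"D{i:04d}", **kwargs)
        )
    return subjects


# ---------------------------------------------------------------------------
# tabular benchmarks


def make_tabular(spec: TabularSpec) -> tuple[pd.DataFrame, set[int]]:
    """Two-class feature table with a known informative subset.

    The first class (label 0) is pure noise N(0, noise_sd²) in every column;
    in the second class (label 1) the ``n_informative`` first columns are
    shifted by ``effect_size`` standard deviations. Returns the table (with a
    trailing ``label`` column) and the set of informative column indices.
    """
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    y = np.repeat([0, 1], spec.n_per_class)
    informative = set(range(spec.n_informative))
    shift = spec.effect_size * spec.noise_sd
    for j in informative:
        X[y == 1, j] += shift
    cols = [f"f{j:03d}" for j in range(spec.n_features)]
    df = pd.DataFrame(X, columns=cols)
    df["label"] = y
    return df, informative


# ---------------------------------------------------------------------------
# on-disk representation: CSV grids + CSV masks + JSON manifest


def write_subject(record: SubjectRecord, outdir: str | Path) -> dict:
    """Write one subject as CSV temperature/mask grids plus manifest entry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entry = {"subject_id": record.subject_id, "label": record.label, "seed": record.seed, "files": {}}
    for side in ("L", "R"):
        tm, mask = record.foot(side)
        tpath = outdir / f"{record.subject_id}_{side}_temp.csv"
        mpath = outdir / f"{record.subject_id}_{side}_mask.csv"
        np.savetxt(tpath, tm.grid, delimiter=",", fmt="%.6f")
        np.savetxt(mpath, mask, delimiter=",", fmt="%d")
        entry["files"][side] = {"temp": tpath.name, "mask": mpath.name}
    return entry


def write_cohort(subjects: list[SubjectRecord], outdir: str | Path) -> Path:
    """Write a cohort and its JSON manifest; returns the manifest path."""
    outdir = Path(outdir)
    entries = [write_subject(s, outdir) for s in subjects]
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({"subjects": entries}, indent=2))
    return manifest


def read_subject(entry: dict, indir: str | Path) -> SubjectRecord:
    indir = Path(indir)
    feet = {}
    for side in ("L", "R"):
        grid = np.loadtxt(indir / entry["files"][side]["temp"], delimiter=",")
        mask = np.loadtxt(indir / entry["files"][side]["mask"], delimiter=",").astype(np.int64)
        feet[side] = (TemperatureMap(grid=grid, valid_mask=mask != BACKGROUND), mask)
    return SubjectRecord(
        subject_id=entry["subject_id"],
        label=entry["label"],
        left=feet["L"][0],
        left_mask=feet["L"][1],
        right=feet["R"][0],
        right_mask=feet["R"][1],
        seed=entry.get("seed"),
    )


def read_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    manifest_path = Path(manifest_path)
    data = json.loads(manifest_path.read_text())
    return [read_subject(e, manifest_path.parent) for e in data["subjects"]]
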