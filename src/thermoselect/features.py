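"""Per-angiosome thermal feature extraction from plantar thermograms.

For each foot and each region (the four angiosomes MPA/LPA/MCA/LCA plus the
entire foot) the following features are computed:

* six summary statistics — mean, std, max, min, skewness, kurtosis;
* NTR occupancy — the fraction of region pixels falling in each of ten fixed
  normalized temperature ranges covering [18, 37) °C;
* ET — the estimated temperature, the occupancy-weighted mean of the NTR
  classmarks (interval midpoints);
* HSE — the hot spot estimator, the classmark of the hottest NTR class with
  meaningful occupancy.

Per foot, the whole-foot TCI (mean absolute deviation of the four angiosome
mean temperatures from control references) and the highest temperature are
added; per region, the unsigned inter-foot ET difference (ETD).

Feature names follow the ``<side>_<region>_<variable>`` convention with the
region descriptor dropped for whole-foot features and the side prefix dropped
for the inter-foot ETDs (e.g. ``R_LPA_min``, ``L_MPA_NTR_C3``, ``Foot_ETD``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import (
    ANGIOSOME_LABELS,
    ANGIOSOME_NAMES,
    BACKGROUND,
    SubjectRecord,
    TemperatureMap,
)

# ---------------------------------------------------------------------------
# NTR class table


@dataclass(frozen=True)
class ClassRecord:
    class_id: str
    ntr_name: str
    lo: float  # inclusive, °C
    hi: float  # exclusive, °C

    @property
    def classmark(self) -> float:
        return (self.lo + self.hi) / 2.0


@dataclass(frozen=True)
class ClassTable:
    """Ordered NTR temperature intervals partitioning [lo, hi) °C."""

    records: tuple[ClassRecord, ...]

    def __post_init__(self):
        if not self.records:
            raise ValueError("empty class table")
        for a, b in zip(self.records, self.records[1:]):
            if not np.isclose(a.hi, b.lo):
                raise ValueError(f"gap/overlap between {a.class_id} and {b.class_id}")

    @property
    def edges(self) -> np.ndarray:
        return np.array([r.lo for r in self.records] + [self.records[-1].hi])

    @property
    def classmarks(self) -> np.ndarray:
        return np.array([r.classmark for r in self.records])

    @property
    def names(self) -> list[str]:
        return [r.ntr_name for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def default_class_table() -> ClassTable:
    """The ten-class NTR table over [18, 37) °C.

    C1 and C2 span 4 °C each (the cold range typical of healthy segmented
    feet), C3–C9 span 1 °C, and C10 spans [33, 37) °C.
    """
    bounds = [18.0, 22.0, 26.0, 27.0, 28.0, 29.0, 30.0, 31.0, 32.0, 33.0, 37.0]
    return ClassTable(
        tuple(
            ClassRecord(f"C{i + 1}", f"NTR_C{i + 1}", lo, hi)
            for i, (lo, hi) in enumerate(zip(bounds, bounds[1:]))
        )
    )


#: per-angiosome control mean temperatures (°C), INAOE control group
DEFAULT_REFERENCE_TEMPS = {"MPA": 25.8, "LPA": 25.7, "MCA": 26.4, "LCA": 26.1}
#: control-group SDs, kept alongside for reference
DEFAULT_REFERENCE_SDS = {"MPA": 1.4, "LPA": 1.3, "MCA": 1.3, "LCA": 1.4}


# ---------------------------------------------------------------------------
# elementary features

STAT_NAMES = ("mean", "std", "max", "min", "skew", "kurtosis")


def summary_stats(values: np.ndarray, region: str = "region") -> dict[str, float]:
    """Mean, population std, max, min, skewness and (non-excess) kurtosis.

    Skewness and kurtosis are the standardized central moments m3/m2^1.5 and
    m4/m2²; a constant region returns 0 for both by convention so that
    feature vectors stay total.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError(f"empty region: {region}")
    if not np.isfinite(values).all():
        raise ValueError(f"non-finite temperatures in region {region}")
    mean = values.mean()
    centered = values - mean
    m2 = np.mean(centered**2)
    std = np.sqrt(m2)
    if std < 1e-12:
        skew = kurt = 0.0
    else:
        skew = np.mean(centered**3) / m2**1.5
        kurt = np.mean(centered**4) / m2**2
    return {
        "mean": mean,
        "std": std,
        "max": values.max(),
        "min": values.min(),
        "skew": skew,
        "kurtosis": kurt,
    }


def assign_class(temperature: float, table: ClassTable | None = None) -> str:
    """Class id of the half-open NTR interval containing the temperature.

    Out-of-range values saturate into the first/last class.
    """
    if table is None:
        table = default_class_table()
    if not np.isfinite(temperature):
        raise ValueError(f"non-finite temperature: {temperature}")
    edges = table.edges
    idx = int(np.searchsorted(edges, temperature, side="right")) - 1
    idx = min(max(idx, 0), len(table) - 1)
    return table.records[idx].class_id


def ntr_occupancy(values: np.ndarray, table: ClassTable | None = None) -> np.ndarray:
    """Fraction of region pixels per NTR class; fractions sum to 1."""
    if table is None:
        table = default_class_table()
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty region for NTR occupancy")
    if not np.isfinite(values).all():
        raise ValueError("non-finite temperatures in NTR occupancy")
    edges = table.edges
    idx = np.searchsorted(edges, values, side="right") - 1
    idx = np.clip(idx, 0, len(table) - 1)  # saturation into C1 / C_last
    counts = np.bincount(idx, minlength=len(table)).astype(float)
    return counts / values.size


def estimated_temperature(occupancy: np.ndarray, table: ClassTable | None = None) -> float:
    """ET: occupancy-weighted average of the classmarks."""
    if table is None:
        table = default_class_table()
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.shape != (len(table),):
        raise ValueError(f"occupancy must have {len(table)} entries")
    if abs(occupancy.sum() - 1.0) > 1e-9:
        raise ValueError(f"occupancy fractions sum to {occupancy.sum()}, not 1")
    return float(occupancy @ table.classmarks)


def etd(et_left: float, et_right: float) -> float:
    """ETD: unsigned inter-foot estimated temperature difference."""
    if not (np.isfinite(et_left) and np.isfinite(et_right)):
        raise ValueError("non-finite ET")
    return abs(et_left - et_right)


def hot_spot_estimator(
    occupancy: np.ndarray,
    table: ClassTable | None = None,
    min_occupancy: float = 0.05,
) -> float:
    """HSE: classmark of the hottest class whose occupancy reaches the floor.

    Falls back to the hottest occupied class when no class reaches
    ``min_occupancy``.
    """
    if table is None:
        table = default_class_table()
    occupancy = np.asarray(occupancy, dtype=float)
    if not (occupancy > 0).any():
        raise ValueError("all-zero occupancy")
    marks = table.classmarks
    passing = np.nonzero(occupancy >= min_occupancy)[0]
    if passing.size:
        return float(marks[passing[-1]])
    return float(marks[np.nonzero(occupancy > 0)[0][-1]])


def thermal_change_index(
    angiosome_means: dict[str, float],
    refs: dict[str, float] | None = None,
) -> tuple[dict[str, float], float]:
    """TCI: absolute deviation of angiosome means from control references.

    Returns per-angiosome TCI values and the whole-foot TCI (their mean).
    The reference strategy is swappable: pass any {angiosome: mean °C} map.
    """
    if refs is None:
        refs = DEFAULT_REFERENCE_TEMPS
    per = {}
    for name in ANGIOSOME_NAMES:
        if name not in angiosome_means or not np.isfinite(angiosome_means[name]):
            raise ValueError(f"missing or non-finite mean for angiosome {name}")
        per[name] = abs(angiosome_means[name] - refs[name])
    return per, float(np.mean(list(per.values())))


# ---------------------------------------------------------------------------
# full feature vectors

#: region keys in extraction order; None denotes the entire foot
_REGIONS: tuple[str | None, ...] = ("MPA", "LPA", "MCA", "LCA", None)


def feature_schema(table: ClassTable | None = None) -> list[str]:
    """The ordered list of feature names produced by :func:`extract_features`."""
    if table is None:
        table = default_class_table()
    names: list[str] = []
    for side in ("L", "R"):
        for region in _REGIONS:
            prefix = f"{side}_{region}_" if region else f"{side}_"
            names += [prefix + s for s in STAT_NAMES]
            names += [prefix + "ET", prefix + "HSE"]
            names += [prefix + n for n in table.names]
        names += [f"{side}_TCI", f"{side}_highest"]
    for region in _REGIONS:
        names.append(f"{region}_ETD" if region else "Foot_ETD")
    return names


def _region_values(tm: TemperatureMap, mask: np.ndarray, region: str | None) -> np.ndarray:
    if region is None:
        sel = mask != BACKGROUND
    else:
        sel = mask == ANGIOSOME_LABELS[region]
    vals = tm.grid[sel]
    if vals.size == 0:
        raise ValueError(f"empty region: {region or 'entire foot'}")
    return vals


def extract_features(
    subject: SubjectRecord,
    table: ClassTable | None = None,
    refs: dict[str, float] | None = None,
    hse_floor: float = 0.05,
) -> dict[str, float]:
    """All thermal features of one subject as an ordered name → value map."""
    if table is None:
        table = default_class_table()
    out: dict[str, float] = {}
    ets: dict[tuple[str, str | None], float] = {}
    for side in ("L", "R"):
        tm, mask = subject.foot(side)
        means = {}
        for region in _REGIONS:
            vals = _region_values(tm, mask, region)
            prefix = f"{side}_{region}_" if region else f"{side}_"
            stats = summary_stats(vals, region=f"{side}_{region or 'foot'}")
            for s in STAT_NAMES:
                out[prefix + s] = float(stats[s])
            occ = ntr_occupancy(vals, table)
            et_val = estimated_temperature(occ, table)
            out[prefix + "ET"] = et_val
            out[prefix + "HSE"] = hot_spot_estimator(occ, table, hse_floor)
            for ntr_name, frac in zip(table.names, occ):
                out[prefix + ntr_name] = float(frac)
            ets[(side, region)] = et_val
            if region is not None:
                means[region] = stats["mean"]
        _, foot_tci = thermal_change_index(means, refs)
        out[f"{side}_TCI"] = foot_tci
        out[f"{side}_highest"] = float(tm.foot_values.max())
    for region in _REGIONS:
        name = f"{region}_ETD" if region else "Foot_ETD"
        out[name] = etd(ets[("L", region)], ets[("R", region)])
    return out


def extract_feature_table(
    subjects: list[SubjectRecord],
    table: ClassTable | None = None,
    refs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Feature table: one row per subject, schema columns plus a label column.

    Labels are encoded 0 = healthy, 1 = diabetic.
    """
    rows = []
    for s in subjects:
        row = extract_features(s, table=table, refs=refs)
        row["label"] = 1 if s.label == "diabetic" else 0
        rows.append(row)
    df = pd.DataFrame(rows, index=[s.subject_id for s in subjects])
    schema = feature_schema(table)
    return df[schema + ["label"]]
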