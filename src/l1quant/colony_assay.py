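"""Colony-based retrotransposition assay quantification.

Stained plates from the cultured-cell retrotransposition assay (G418
selection of cells carrying a retrotransposed neo reporter) are segmented,
candidate regions are measured, and colonies are called by three
morphometric gates at the published thresholds: minimum equivalent
diameter 194.5 µm, circularity ≥ 0.45 and gray-level texture difference
moment ≤ 2.75 (all bounds inclusive).  Colony counts then run through the
correction chain: mean over three technical replicates, division by the
transfection efficiency, division by a co-selected reporter plasmid, and
conversion to an efficiency percentage relative to a baseline condition
set at 100%.

The texture difference moment is implemented as gray-level co-occurrence
matrix (GLCM) contrast ``sum((i-j)^2 p(i,j))`` at distance 1 averaged over
4 directions on 8 gray levels, after min-max rescaling within the region;
only pixel pairs that both fall inside the region contribute (the
vendor formula behind the published threshold is unpublished, so every
GLCM parameter is exposed in :class:`GlcmConfig`).  Perimeter uses the
Crofton estimator (4 directions), named in output metadata because the
estimator choice shifts circularity: Crofton converges to the true
perimeter for smooth shapes, so digitised disks approach circularity 1 as
they grow, which boundary-segment counting does not achieve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "GlcmConfig",
    "GateThresholds",
    "AssayResult",
    "segment_plate",
    "region_features",
    "gate_colonies",
    "transfection_efficiency",
    "corrected_efficiency",
    "quantify_plate_set",
    "unpaired_t_test",
]

PERIMETER_ESTIMATOR = "crofton-4-directions"


@dataclass
class GlcmConfig:
    """Parameters of the texture difference moment (GLCM contrast)."""

    levels: int = 8
    distance: int = 1
    #: (dy, dx) offsets; the 4 standard directions at distance 1
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class GateThresholds:
    """Published colony gates; comparisons are inclusive at every bound."""

    min_diameter_um: float = 194.5
    min_circularity: float = 0.45
    max_texture_dm: float = 2.75


@dataclass
class AssayResult:
    """One condition's colony counts through the correction chain."""

    condition: str
    raw_counts: tuple[int, ...]
    mean_count: float
    transfection_efficiency: float
    adjusted_mean: float
    reporter_adjusted_mean: float
    corrected_mean: float
    efficiency_percent: float


def segment_plate(image: np.ndarray, pixel_size_um: float) -> tuple[np.ndarray, int]:
    """Segment a grayscale plate image into candidate regions.

    Global Otsu threshold (bright foreground on dark background), hole
    filling, 8-connected labelling; regions touching the border are kept.
    A constant image yields zero regions with a warning.

    Returns ``(labels, n_regions)``.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel (2-D) image")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if img.min() == img.max():
        warnings.warn("constant image: no foreground to segment", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32), 0
    mask = img > threshold_otsu(img)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    return labels.astype(np.int32), n


def _masked_glcm_contrast(patch: np.ndarray, mask: np.ndarray, cfg: GlcmConfig) -> float:
    """GLCM contrast over pixel pairs fully inside the region mask.

    Gray levels are min-max quantised to ``cfg.levels`` bins within the
    region; a flat region has contrast 0 by definition.  Each offset's
    symmetric co-occurrence matrix is normalised before contrast, and the
    directional contrasts are averaged.
    """
    vals = patch[mask].astype(float)
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        return 0.0
    q = np.zeros(patch.shape, dtype=np.int64)
    q[mask] = np.minimum(
        ((patch[mask] - vmin) / (vmax - vmin) * cfg.levels).astype(np.int64),
        cfg.levels - 1,
    )
    contrasts = []
    d = cfg.distance
    for dy, dx in cfg.offsets:
        dy, dx = dy * d, dx * d
        h, w = patch.shape
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        ys2 = slice(max(0, dy), min(h, h + dy))
        xs2 = slice(max(0, dx), min(w, w + dx))
        both = mask[ys, xs] & mask[ys2, xs2]
        if not both.any():
            continue
        a = q[ys, xs][both]
        b = q[ys2, xs2][both]
        # symmetric pairs: each (a,b) also counted as (b,a); contrast is
        # already symmetric in (i-j)^2 so normalisation cancels
        contrasts.append(float(np.mean((a - b) ** 2)))
    return float(np.mean(contrasts)) if contrasts else 0.0


def region_features(
    labels: np.ndarray,
    image: np.ndarray,
    pixel_size_um: float,
    glcm: GlcmConfig | None = None,
) -> pd.DataFrame:
    """Morphometric features for every labelled region.

    Columns: ``label, area_px, equivalent_diameter_um, perimeter_px,
    circularity, texture_difference_moment, perimeter_estimator``.
    Equivalent diameter is ``2*sqrt(area/pi) * pixel_size``; circularity is
    ``4*pi*area/perimeter^2`` (≈ 1 for a disk, slightly above 1 possible
    from digitisation; a degenerate zero-perimeter region reports 1.0).
    """
    glcm = glcm or GlcmConfig()
    img = np.asarray(image)
    rows = []
    for region in measure.regionprops(labels):
        area = float(region.area)
        perim = float(measure.perimeter_crofton(region.image, directions=4))
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 1.0
        sl = region.slice
        patch = img[sl]
        tdm = _masked_glcm_contrast(patch, region.image, glcm)
        rows.append(
            {
                "label": region.label,
                "area_px": area,
                "equivalent_diameter_um": 2.0 * np.sqrt(area / np.pi) * pixel_size_um,
                "perimeter_px": perim,
                "circularity": circ,
                "texture_difference_moment": tdm,
                "centroid_y": region.centroid[0],
                "centroid_x": region.centroid[1],
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "label", "area_px", "equivalent_diameter_um", "perimeter_px",
            "circularity", "texture_difference_moment", "centroid_y", "centroid_x",
        ],
    )
    df.attrs["perimeter_estimator"] = PERIMETER_ESTIMATOR
    return df


def gate_colonies(
    features: pd.DataFrame, gates: GateThresholds | None = None
) -> tuple[pd.Series, int]:
    """Apply the three inclusive morphometric gates; return flags and count."""
    gates = gates or GateThresholds()
    flags = (
        (features["equivalent_diameter_um"] >= gates.min_diameter_um)
        & (features["circularity"] >= gates.min_circularity)
        & (features["texture_difference_moment"] <= gates.max_texture_dm)
    )
    return flags.rename("is_colony"), int(flags.sum())


def transfection_efficiency(n_positive: int, n_total: int) -> float:
    """Fraction of reporter-positive (EGFP+) cells over total counted."""
    if n_total <= 0 or n_positive > n_total:
        raise ValueError("need 0 < n_positive <= n_total")
    if n_positive <= 0:
        raise ValueError("no transfected cells detected; condition unusable for adjustment")
    return n_positive / n_total


def corrected_efficiency(
    l1_counts,
    l1_teff: float,
    reporter_counts,
    reporter_teff: float,
    baseline: "AssayResult | None" = None,
    condition: str = "condition",
) -> AssayResult:
    """Run the colony-count correction chain for one condition.

    ``adjusted = mean(counts)/transfection_efficiency`` for both the L1 and
    the co-selected reporter plasmid; ``corrected = adjusted_L1 /
    adjusted_reporter``; the efficiency percentage is relative to
    ``baseline`` (itself reported as exactly 100% when ``baseline`` is
    None).
    """
    l1_counts = tuple(int(c) for c in l1_counts)
    reporter_counts = tuple(int(c) for c in reporter_counts)
    for teff in (l1_teff, reporter_teff):
        if not 0 < teff <= 1:
            raise ValueError("transfection efficiencies must lie in (0, 1]")
    mean_count = float(np.mean(l1_counts))
    adjusted = mean_count / l1_teff
    reporter_adjusted = float(np.mean(reporter_counts)) / reporter_teff
    if reporter_adjusted == 0:
        raise ValueError("reporter adjusted mean is zero; correction undefined")
    corrected = adjusted / reporter_adjusted
    if baseline is None:
        percent = 100.0
    else:
        if baseline.corrected_mean == 0:
            raise ValueError("baseline corrected mean is zero")
        percent = 100.0 * corrected / baseline.corrected_mean
    return AssayResult(
        condition=condition,
        raw_counts=l1_counts,
        mean_count=mean_count,
        transfection_efficiency=l1_teff,
        adjusted_mean=adjusted,
        reporter_adjusted_mean=reporter_adjusted,
        corrected_mean=corrected,
        efficiency_percent=percent,
    )


def count_colonies(
    image: np.ndarray,
    pixel_size_um: float,
    gates: GateThresholds | None = None,
    glcm: GlcmConfig | None = None,
) -> tuple[int, pd.DataFrame]:
    """Segment one plate image and count gated colonies.

    Returns ``(count, audit)`` where the audit table carries every region's
    features plus its ``is_colony`` verdict.
    """
    labels, n = segment_plate(image, pixel_size_um)
    feats = region_features(labels, image, pixel_size_um, glcm)
    if n == 0:
        feats["is_colony"] = pd.Series(dtype=bool)
        return 0, feats
    flags, count = gate_colonies(feats, gates)
    feats["is_colony"] = flags
    return count, feats


def quantify_plate_set(
    conditions: dict,
    baseline: str,
    pixel_size_um: float,
    gates: GateThresholds | None = None,
    glcm: GlcmConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a full assay: plates per condition through the whole chain.

    ``conditions`` maps a condition label to a dict with keys
    ``l1_images`` (3 plate images), ``l1_teff``, ``reporter_images`` (3
    plates of the co-selected reporter) and ``reporter_teff``.  The
    ``baseline`` condition is set to 100%.

    Returns ``(assay_table, audit_table)``; the audit table lists every
    segmented region of every plate with its features and verdict.
    """
    if baseline not in conditions:
        raise ValueError(f"baseline condition {baseline!r} missing from input")
    audits = []
    per_condition: dict[str, tuple[tuple[int, ...], float, tuple[int, ...], float]] = {}
    for label, spec in conditions.items():
        l1_counts, rep_counts = [], []
        for kind, images, sink in (
            ("l1", spec["l1_images"], l1_counts),
            ("reporter", spec["reporter_images"], rep_counts),
        ):
            if len(images) != 3:
                raise ValueError(f"{label}/{kind}: expected 3 technical-replicate plates")
            for i, img in enumerate(images, start=1):
                count, audit = count_colonies(img, pixel_size_um, gates, glcm)
                audit.insert(0, "condition", label)
                audit.insert(1, "plate", f"{kind}_{i}")
                audits.append(audit)
                sink.append(count)
        per_condition[label] = (
            tuple(l1_counts), spec["l1_teff"], tuple(rep_counts), spec["reporter_teff"]
        )

    base_l1, base_lt, base_rep, base_rt = per_condition[baseline]
    base_result = corrected_efficiency(base_l1, base_lt, base_rep, base_rt, None, baseline)
    results = []
    for label, (l1c, lt, repc, rt) in per_condition.items():
        if label == baseline:
            results.append(base_result)
        else:
            results.append(corrected_efficiency(l1c, lt, repc, rt, base_result, label))
    assay = pd.DataFrame([vars(r) for r in results])
    audit = pd.concat(audits, ignore_index=True) if audits else pd.DataFrame()
    return assay, audit


def unpaired_t_test(a, b) -> tuple[float, float]:
    """Two-tailed unpaired Student's t-test (figure-legend style); (t, p)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=True)
    return float(t), float(p)
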