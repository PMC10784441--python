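"""Handcrafted radiomics features (116 per region) from the X/XL/XH triple.

The catalog is frozen by name and order: 8 shape features computed once on
the mask, plus — for each of the three image variants X, XL, XH — 14
histogram features, 13 gray-level co-occurrence matrix (GLCM) features, 8
gray-level run-length matrix (GLRLM) features and 1 differential
box-counting fractal dimension: 8 + 3 x 36 = 116.  Formulas follow the
image biomarker standardization initiative conventions for 2D, fixed-bin-
number discretization, with explicit degenerate-case rules so every valid
input yields a complete vector.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from skimage import measure

N_BINS_DEFAULT = 32
GLCM_DIRECTIONS = ((0, 1), (-1, 1), (1, 0), (1, 1))  # 0, 45, 90, 135 degrees

SHAPE_STATS = (
    "area",
    "perimeter",
    "perimeter_area_ratio",
    "circularity",
    "major_axis",
    "minor_axis",
    "elongation",
    "solidity",
)
HIST_STATS = (
    "mean",
    "variance",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "maximum",
    "range",
    "interquartile_range",
    "mean_absolute_deviation",
    "energy",
    "entropy",
    "uniformity",
)
GLCM_STATS = (
    "contrast",
    "correlation",
    "energy",
    "entropy",
    "homogeneity",
    "homogeneity2",
    "dissimilarity",
    "cluster_shade",
    "cluster_prominence",
    "autocorrelation",
    "sum_average",
    "sum_entropy",
    "maximum_probability",
)
GLRLM_STATS = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE", "LRHGLE")
VARIANTS = ("X", "XL", "XH")


def catalog() -> list[str]:
    """The frozen, ordered list of the 116 handcrafted feature names."""
    names = [f"Shape_{s}" for s in SHAPE_STATS]
    for v in VARIANTS:
        names += [f"{v}_H_{s}" for s in HIST_STATS]
        names += [f"{v}_GLCM_{s}" for s in GLCM_STATS]
        names += [f"{v}_GLRLM_{s}" for s in GLRLM_STATS]
        names.append(f"{v}_fractal_dimension")
    return names


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0*log0 := 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def discretize(img: np.ndarray, mask: np.ndarray, n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """Map in-ROI intensities to integer levels 1..n_bins (equal-width bins).

    Bins span the ROI min-max range (fixed bin number).  A constant ROI maps
    to level 1 everywhere.  Pixels outside the mask are labeled 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    vals = np.asarray(img, dtype=np.float64)[mask]
    lo, hi = vals.min(), vals.max()
    labels = np.zeros(mask.shape, dtype=np.int64)
    if hi == lo:
        labels[mask] = 1
        return labels
    lv = np.floor((vals - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    labels[mask] = np.minimum(lv, n_bins)
    return labels


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------


def shape_features(mask: np.ndarray, spacing: float = 1.0) -> dict[str, float]:
    """8 mask-only descriptors of the largest connected component (mm / mm2)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(lab)
    region = max(props, key=lambda r: r.area)
    area = region.area * spacing**2
    perim = region.perimeter * spacing
    major = region.axis_major_length * spacing
    minor = region.axis_minor_length * spacing
    circ = 4.0 * np.pi * area / perim**2 if perim > 0 else np.nan
    elong = major / minor if minor > 0 else np.inf
    return {
        "area": float(area),
        "perimeter": float(perim),
        "perimeter_area_ratio": float(perim / area),
        "circularity": float(circ),
        "major_axis": float(major),
        "minor_axis": float(minor),
        "elongation": float(elong),
        "solidity": float(region.solidity),
    }


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------


def histogram_features(
    img: np.ndarray, mask: np.ndarray, n_bins: int = N_BINS_DEFAULT
) -> dict[str, float]:
    """14 first-order statistics of in-ROI intensities.

    Entropy (bits) and uniformity are computed on the equal-width discretized
    histogram; all moments are population moments.  A constant ROI yields
    variance 0, skewness/kurtosis 0 (convention), entropy 0, uniformity 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    v = np.asarray(img, dtype=np.float64)[mask]
    var = float(v.var())
    if var > 0:
        # catastrophic cancellation on near-constant data can yield NaN
        skw = float(np.nan_to_num(stats.skew(v), nan=0.0))
        kur = float(np.nan_to_num(stats.kurtosis(v, fisher=False), nan=0.0))
    else:
        skw = kur = 0.0
    labels = discretize(img, mask, n_bins)[mask]
    p = np.bincount(labels, minlength=n_bins + 1)[1:].astype(np.float64)
    p /= p.sum()
    q25, q75 = np.percentile(v, [25, 75])
    return {
        "mean": float(v.mean()),
        "variance": var,
        "standard_deviation": float(np.sqrt(var)),
        "skewness": skw,
        "kurtosis": kur,
        "median": float(np.median(v)),
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "range": float(v.max() - v.min()),
        "interquartile_range": float(q75 - q25),
        "mean_absolute_deviation": float(np.abs(v - v.mean()).mean()),
        "energy": float((v**2).sum()),
        "entropy": float(-_xlog2(p).sum()),
        "uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_matrix(
    labels: np.ndarray,
    n_bins: int = N_BINS_DEFAULT,
    distance: int = 1,
    directions=GLCM_DIRECTIONS,
) -> np.ndarray:
    """Direction-averaged symmetric normalized co-occurrence matrix.

    Only pixel pairs with both members inside the ROI (label > 0) count.
    Each direction's matrix is normalized to sum 1 before averaging;
    directions with no valid pair are skipped.  If no direction has a pair
    (single-pixel ROI) the all-zero matrix is returned.
    """
    labels = np.asarray(labels, dtype=np.int64)
    h, w = labels.shape
    mats = []
    for dr, dc in directions:
        dr, dc = dr * distance, dc * distance
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = labels[r0:r1, c0:c1]
        b = labels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        m = np.zeros((n_bins, n_bins), dtype=np.float64)
        np.add.at(m, (a[ok] - 1, b[ok] - 1), 1.0)
        m = m + m.T  # symmetric
        mats.append(m / m.sum())
    if not mats:
        return np.zeros((n_bins, n_bins), dtype=np.float64)
    return np.mean(mats, axis=0)


def glcm_features_from_matrix(p: np.ndarray) -> dict[str, float]:
    """13 Haralick-style statistics of a normalized symmetric GLCM.

    Degenerate conventions: entropy uses 0*log0 := 0; correlation of a
    zero-variance matrix is 1.
    """
    n = p.shape[0]
    lv = np.arange(1, n + 1, dtype=np.float64)
    i = lv[:, None]
    j = lv[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mx = float((lv * px).sum())
    my = float((lv * py).sum())
    sx = float(np.sqrt(((lv - mx) ** 2 * px).sum()))
    sy = float(np.sqrt(((lv - my) ** 2 * py).sum()))
    diff = i - j
    if sx > 0 and sy > 0:
        corr = float(((i - mx) * (j - my) * p).sum() / (sx * sy))
    else:
        corr = 1.0
    # distribution of i+j over 2..2n
    k = np.arange(2, 2 * n + 1, dtype=np.float64)
    pxy = np.zeros(2 * n - 1)
    idx = np.add.outer(np.arange(n), np.arange(n)).ravel()
    np.add.at(pxy, idx, p.ravel())
    csum = i + j - mx - my
    return {
        "contrast": float((diff**2 * p).sum()),
        "correlation": corr,
        "energy": float((p**2).sum()),
        "entropy": float(-_xlog2(p).sum()),
        "homogeneity": float((p / (1.0 + np.abs(diff))).sum()),
        "homogeneity2": float((p / (1.0 + diff**2)).sum()),
        "dissimilarity": float((np.abs(diff) * p).sum()),
        "cluster_shade": float((csum**3 * p).sum()),
        "cluster_prominence": float((csum**4 * p).sum()),
        "autocorrelation": float((i * j * p).sum()),
        "sum_average": float((k * pxy).sum()),
        "sum_entropy": float(-_xlog2(pxy).sum()),
        "maximum_probability": float(p.max()),
    }


def glcm_features(
    img: np.ndarray,
    mask: np.ndarray,
    n_bins: int = N_BINS_DEFAULT,
    distance: int = 1,
    directions=GLCM_DIRECTIONS,
) -> dict[str, float]:
    labels = discretize(img, mask, n_bins)
    return glcm_features_from_matrix(glcm_matrix(labels, n_bins, distance, directions))


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _direction_lines(labels: np.ndarray, direction: tuple[int, int]):
    """Yield the 1D label sequences of an array along one of the 4 directions."""
    h, w = labels.shape
    dr, dc = direction
    if (dr, dc) == (0, 1):
        yield from labels
    elif (dr, dc) == (1, 0):
        yield from labels.T
    elif (dr, dc) == (1, 1):
        for off in range(-h + 1, w):
            yield np.diagonal(labels, offset=off)
    elif (dr, dc) == (-1, 1):
        fl = np.flipud(labels)
        for off in range(-h + 1, w):
            yield np.diagonal(fl, offset=off)
    else:
        raise ValueError(f"unsupported run direction {direction}")


def glrlm_matrix(labels: np.ndarray, n_bins: int, direction: tuple[int, int]) -> np.ndarray:
    """Run-length counts P[gray level - 1, run length - 1] for one direction.

    Pixels outside the ROI (label 0) break runs.  All lines of the direction
    are concatenated with a zero separator and run-length encoded in one
    vectorized pass.
    """
    h, w = labels.shape
    max_run = max(h, w)
    m = np.zeros((n_bins, max_run), dtype=np.float64)
    sep = np.zeros(1, dtype=np.int64)
    pieces = []
    for line in _direction_lines(labels, direction):
        pieces.append(np.ascontiguousarray(line))
        pieces.append(sep)
    seq = np.concatenate(pieces)
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate([[0], change + 1])
    lengths = np.diff(np.concatenate([starts, [len(seq)]]))
    vals = seq[starts]
    keep = vals > 0
    np.add.at(m, (vals[keep] - 1, lengths[keep] - 1), 1.0)
    return m


def glrlm_features_from_matrix(m: np.ndarray, n_pixels: int) -> dict[str, float]:
    nr = m.sum()
    if nr == 0:
        raise ValueError("no runs: empty ROI")
    lv = np.arange(1, m.shape[0] + 1, dtype=np.float64)[:, None]
    rl = np.arange(1, m.shape[1] + 1, dtype=np.float64)[None, :]
    return {
        "SRE": float((m / rl**2).sum() / nr),
        "LRE": float((m * rl**2).sum() / nr),
        "GLN": float((m.sum(axis=1) ** 2).sum() / nr),
        "RLN": float((m.sum(axis=0) ** 2).sum() / nr),
        "RP": float(nr / n_pixels),
        "LGRE": float((m / lv**2).sum() / nr),
        "HGRE": float((m * lv**2).sum() / nr),
        "LRHGLE": float((m * lv**2 * rl**2).sum() / nr),
    }


def glrlm_features(
    img: np.ndarray,
    mask: np.ndarray,
    n_bins: int = N_BINS_DEFAULT,
    directions=GLCM_DIRECTIONS,
) -> dict[str, float]:
    """8 run-length statistics averaged over the four 2D directions."""
    mask = np.asarray(mask, dtype=bool)
    labels = discretize(img, mask, n_bins)
    n_pixels = int(mask.sum())
    per_dir = [
        glrlm_features_from_matrix(glrlm_matrix(labels, n_bins, d), n_pixels) for d in directions
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_STATS}


# ---------------------------------------------------------------------------
# fractal
# ---------------------------------------------------------------------------


def fractal_feature(
    img: np.ndarray,
    mask: np.ndarray,
    box_sizes=(2, 4, 8, 16),
    gray_levels: int = 256,
) -> float:
    """Differential box-counting dimension of the ROI intensity surface.

    The mask bounding box (>= 8x8 required) is cropped, out-of-ROI pixels
    mean-filled, intensities rescaled to [0, gray_levels - 1]; for each box
    size s the surface is covered by columns of height s * G / M (M = larger
    crop dimension) and the dimension is the slope of log N(s) versus
    log(1/s).  A flat surface gives slope 2 (the topological dimension).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    crop = np.asarray(img, dtype=np.float64)[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1].copy()
    mcrop = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    if min(crop.shape) < 8:
        raise ValueError("ROI bounding box must be at least 8x8 for box counting")
    crop[~mcrop] = crop[mcrop].mean()
    lo, hi = crop.min(), crop.max()
    g = (crop - lo) / (hi - lo) * (gray_levels - 1) if hi > lo else np.zeros_like(crop)
    m_dim = max(crop.shape)
    log_inv_s, log_n = [], []
    for s in box_sizes:
        ph = (-g.shape[0]) % s
        pw = (-g.shape[1]) % s
        gp = np.pad(g, ((0, ph), (0, pw)), mode="edge")
        bh, bw = gp.shape[0] // s, gp.shape[1] // s
        blocks = gp.reshape(bh, s, bw, s)
        bmax = blocks.max(axis=(1, 3))
        bmin = blocks.min(axis=(1, 3))
        h = s * gray_levels / m_dim
        nr = np.floor(bmax / h) - np.floor(bmin / h) + 1.0
        log_inv_s.append(np.log(1.0 / s))
        log_n.append(np.log(nr.sum()))
    slope = np.polyfit(log_inv_s, log_n, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------


def extract_handcrafted(study, mask: np.ndarray, n_bins: int = N_BINS_DEFAULT):
    """Extract the full ordered 116-feature vector for one region.

    Shape features are computed once on the mask; histogram/GLCM/GLRLM/
    fractal are computed per variant X, XL, XH.  A family that raises on a
    given input contributes NaNs, and the failure is recorded in the
    returned validity report.

    Returns ``(pandas.Series indexed by catalog(), report dict)``.
    """
    import pandas as pd

    mask = np.asarray(mask, dtype=bool)
    values: dict[str, float] = {}
    report: dict[str, str] = {}

    spacing = study.X.spacing
    try:
        shp = shape_features(mask, spacing)
        values.update({f"Shape_{k}": v for k, v in shp.items()})
    except Exception as exc:  # noqa: BLE001 - recorded, not silenced
        values.update({f"Shape_{k}": np.nan for k in SHAPE_STATS})
        report["Shape"] = str(exc)

    for v in VARIANTS:
        img = study.variant(v).pixels
        for family, stats_names, fn in (
            ("H", HIST_STATS, lambda a: histogram_features(a, mask, n_bins)),
            ("GLCM", GLCM_STATS, lambda a: glcm_features(a, mask, n_bins)),
            ("GLRLM", GLRLM_STATS, lambda a: glrlm_features(a, mask, n_bins)),
        ):
            try:
                feats = fn(img)
                values.update({f"{v}_{family}_{k}": feats[k] for k in stats_names})
            except Exception as exc:  # noqa: BLE001
                values.update({f"{v}_{family}_{k}": np.nan for k in stats_names})
                report[f"{v}_{family}"] = str(exc)
        try:
            values[f"{v}_fractal_dimension"] = fractal_feature(img, mask)
        except Exception as exc:  # noqa: BLE001
            values[f"{v}_fractal_dimension"] = np.nan
            report[f"{v}_fractal"] = str(exc)

    series = pd.Series([values[name] for name in catalog()], index=catalog(), dtype=np.float64)
    return series, report
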