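"""Per-cell morphometric descriptors and the 166-entry patient vector.

Each segmented cell yields 15 scalar geometry/intensity/co-occurrence
descriptors plus four texture histograms (LBP, TFCM, CSAC, texton).  The
patient-level vector reduces the per-cell distributions to moment
statistics:

* 15 scalars x (mean, median, variance, 3 histogram frequencies) = 90
* TFCM 8-bin histogram x (mean, median, variance per bin)         = 24
* CSAC 12 statistics x (mean, variance)                           = 24
* LBP 8-bin histogram x (mean, median, variance per bin)          = 24
* texton 4-bin histogram x (mean per bin)                         = 4

for a total of exactly 166 named entries.  Intensity and texture are
computed on the L channel of the Lab color space rescaled to [0, 255];
the a and b channels additionally enter the 3-channel CSAC statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2lab
from skimage.measure import regionprops, perimeter_crofton
from sklearn.cluster import KMeans

N_GRAY = 32           # gray-level quantization for GLCM and histograms
TFCM_EPS = 2.0        # "equal" tolerance in gray levels for TFCM codes

SCALAR_NAMES = ("area", "axis_ratio", "circularity", "perimeter", "solidity",
                "mean", "std", "kurtosis", "entropy", "energy",
                "contrast", "correlation", "glcm_energy", "homogeneity",
                "skewness")

# Column prefixes of the patient vector, in table order
_PREFIXES = ("area", "axis", "cir", "peri", "solidity", "mean", "std",
             "kurt", "entr", "energy", "contrast", "corr", "engy", "homo",
             "skew")
_SCALAR_FOR_PREFIX = dict(zip(_PREFIXES, SCALAR_NAMES))

PATIENT_FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{p}{i}" for p in _PREFIXES for i in range(1, 7)]
    + [f"tfcm{i}" for i in range(1, 25)]
    + [f"csac{i}" for i in range(1, 25)]
    + [f"lbp{i}" for i in range(1, 25)]
    + [f"t{i}" for i in range(1, 5)]
)
assert len(PATIENT_FEATURE_NAMES) == 166


@dataclass
class CellDescriptor:
    scalars: dict[str, float]
    lbp_hist: np.ndarray
    tfcm_hist: np.ndarray
    csac_vec: np.ndarray
    texton_hist: np.ndarray


@dataclass
class TextonModel:
    filter_bank: list[np.ndarray]
    textons: np.ndarray        # (k, n_filters) cluster centers
    k: int


# ---------------------------------------------------------------- geometry

def geometry_features(mask: np.ndarray,
                      contour: np.ndarray | None = None) -> dict[str, float]:
    """Area, perimeter, circularity, major/minor axis ratio and solidity.

    Perimeter is the polygon arc length when a contour is supplied and the
    Crofton estimate of the binary mask otherwise (plain pixel-edge counts
    overestimate smooth boundaries)."""
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    area = float(mask.sum())
    if contour is not None and len(contour) >= 3:
        per = float(np.linalg.norm(
            np.roll(contour, -1, axis=0) - contour, axis=1).sum())
    else:
        per = float(perimeter_crofton(mask, directions=4))
    props = regionprops(mask.astype(np.uint8))[0]
    minor = props.axis_minor_length
    if minor < 1e-9:
        axis_ratio = 100.0               # degenerate line-like region, capped
    else:
        axis_ratio = props.axis_major_length / minor
    circ = 4 * np.pi * area / per ** 2 if per > 0 else 0.0
    return {
        "area": area,
        "axis_ratio": float(axis_ratio),
        "circularity": float(circ),
        "perimeter": per,
        "solidity": _solidity(mask, area, props),
    }


def _solidity(mask: np.ndarray, area: float, props) -> float:
    """Area over the pixel count of the convex hull, where the hull is
    realized as the set of pixel centers inside the hull polygon of the
    region's pixel centers (boundary inclusive).  This digitization is
    exact for convex digitized shapes — their solidity is 1 — while any
    concavity pulls it strictly below 1."""
    try:
        from scipy.spatial import Delaunay

        ys, xs = np.nonzero(mask)
        tri = Delaunay(np.stack([xs, ys], axis=1))
        gy, gx = np.mgrid[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
        hull_count = int((tri.find_simplex(pts) >= 0).sum())
    except Exception:       # degenerate (collinear) regions
        return float(props.solidity)
    return float(area / hull_count)


# --------------------------------------------------------------- intensity

def _hist32(values: np.ndarray) -> np.ndarray:
    h, _ = np.histogram(values, bins=N_GRAY, range=(0, 256))
    tot = h.sum()
    return h / tot if tot else h.astype(float)


def intensity_features(values: np.ndarray) -> dict[str, float]:
    """First-moment statistics plus histogram entropy/energy of the cell's
    L-channel values (expected on a [0, 255] scale)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 pixels")
    mu = v.mean()
    sd = v.std()                      # population SD
    if sd < 1e-12:
        skew = kurt = 0.0
    else:
        z = (v - mu) / sd
        skew = float((z ** 3).mean())
        kurt = float((z ** 4).mean() - 3.0)
    p = _hist32(v)
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    energy = float((p ** 2).sum())
    return {"mean": float(mu), "std": float(sd), "skewness": skew,
            "kurtosis": kurt, "entropy": entropy, "energy": energy}


# -------------------------------------------------------------------- GLCM

def _quantize(values: np.ndarray) -> np.ndarray:
    return np.clip((np.asarray(values, float) / 256.0 * N_GRAY).astype(int),
                   0, N_GRAY - 1)


def glcm_features(patch: np.ndarray,
                  mask: np.ndarray | None = None) -> dict[str, float]:
    """Haralick contrast, correlation, energy and homogeneity from the
    symmetric 32-level co-occurrence matrix averaged over the (0,1) and
    (1,0) offsets.  Pairs with a masked-out member are skipped."""
    q = _quantize(patch)
    if mask is None:
        mask = np.ones(q.shape, dtype=bool)
    P = np.zeros((N_GRAY, N_GRAY))
    for dy, dx in ((0, 1), (1, 0)):
        a = q[: q.shape[0] - dy, : q.shape[1] - dx]
        b = q[dy:, dx:]
        m = mask[: q.shape[0] - dy, : q.shape[1] - dx] & mask[dy:, dx:]
        np.add.at(P, (a[m], b[m]), 1.0)
        np.add.at(P, (b[m], a[m]), 1.0)
    tot = P.sum()
    if tot == 0:
        return {"contrast": 0.0, "correlation": 0.0,
                "glcm_energy": 1.0, "homogeneity": 1.0}
    P /= tot
    i = np.arange(N_GRAY)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float((P * (ii - jj) ** 2).sum())
    energy = float((P ** 2).sum())
    homog = float((P / (1.0 + (ii - jj) ** 2)).sum())
    pi = P.sum(1)
    mu_i = float((i * pi).sum())
    var_i = float(((i - mu_i) ** 2 * pi).sum())
    if var_i < 1e-12:
        corr = 0.0
    else:
        corr = float(((ii - mu_i) * (jj - mu_i) * P).sum() / var_i)
    return {"contrast": contrast, "correlation": corr,
            "glcm_energy": energy, "homogeneity": homog}


# --------------------------------------------------------------------- LBP

def lbp_features(patch: np.ndarray,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """8-neighbor local binary patterns pooled into 8 equal code-range
    bins.  A neighbor >= center sets its bit (ties code as 1).  Only
    pixels whose full 3x3 neighborhood lies inside the patch and mask
    contribute."""
    p = np.asarray(patch, dtype=float)
    if p.shape[0] < 3 or p.shape[1] < 3:
        raise ValueError("patch must be at least 3x3")
    if mask is None:
        mask = np.ones(p.shape, dtype=bool)
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1),
               (1, 1), (1, 0), (1, -1), (0, -1)]
    center = p[1:-1, 1:-1]
    valid = mask[1:-1, 1:-1].copy()
    code = np.zeros(center.shape, dtype=int)
    for bit, (dy, dx) in enumerate(offsets):
        nb = p[1 + dy: p.shape[0] - 1 + dy, 1 + dx: p.shape[1] - 1 + dx]
        valid &= mask[1 + dy: p.shape[0] - 1 + dy,
                      1 + dx: p.shape[1] - 1 + dx]
        code |= (nb >= center).astype(int) << bit
    codes = code[valid]
    hist = np.zeros(8)
    if codes.size:
        np.add.at(hist, codes // 32, 1.0)
        hist /= codes.size
    return hist


# -------------------------------------------------------------------- TFCM

def tfcm_features(patch: np.ndarray, mask: np.ndarray | None = None,
                  eps: float = TFCM_EPS) -> np.ndarray:
    """Texture-feature-coding histogram pooled into 8 bins.

    For each interior pixel the two neighbors along each of the four
    directions (0, 45, 90, 135 degrees) are compared with the center using
    a 3-level code (less / equal within ``eps`` / greater); the pair of
    codes gives a base-9 digit per direction and the four digits form the
    texture feature number, whose range [0, 6560] is pooled into 8 equal
    bins."""
    p = np.asarray(patch, dtype=float)
    if p.shape[0] < 3 or p.shape[1] < 3:
        raise ValueError("patch must be at least 3x3")
    if mask is None:
        mask = np.ones(p.shape, dtype=bool)
    directions = [((0, -1), (0, 1)),    # 0 deg
                  ((1, -1), (-1, 1)),   # 45 deg
                  ((-1, 0), (1, 0)),    # 90 deg
                  ((-1, -1), (1, 1))]   # 135 deg
    center = p[1:-1, 1:-1]
    valid = mask[1:-1, 1:-1].copy()
    tfn = np.zeros(center.shape, dtype=int)
    H, W = p.shape
    for d, ((dy1, dx1), (dy2, dx2)) in enumerate(directions):
        n1 = p[1 + dy1: H - 1 + dy1, 1 + dx1: W - 1 + dx1]
        n2 = p[1 + dy2: H - 1 + dy2, 1 + dx2: W - 1 + dx2]
        valid &= mask[1 + dy1: H - 1 + dy1, 1 + dx1: W - 1 + dx1]
        valid &= mask[1 + dy2: H - 1 + dy2, 1 + dx2: W - 1 + dx2]
        s1 = np.where(n1 - center > eps, 2,
                      np.where(center - n1 > eps, 0, 1))
        s2 = np.where(n2 - center > eps, 2,
                      np.where(center - n2 > eps, 0, 1))
        tfn += (3 * s1 + s2) * 9 ** d
    vals = tfn[valid]
    hist = np.zeros(8)
    if vals.size:
        bins = np.minimum(vals * 8 // 6561, 7)
        np.add.at(hist, bins, 1.0)
        hist /= vals.size
    return hist


# -------------------------------------------------------------------- CSAC

_CS_PAIRS = (((0, 0), (2, 2)), ((0, 1), (2, 1)),
             ((0, 2), (2, 0)), ((1, 0), (1, 2)))


def csac_features(patch3: np.ndarray,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Center-symmetric auto-correlation statistics over 3x3 units.

    Per channel, every fully-valid 3x3 unit contributes its four
    center-symmetric pixel pairs; over all pairs the statistics are
    SCOV (covariance about the pooled mean), SVR (SCOV normalized by the
    pooled variance), WVAR (mean within-pair half squared difference) and
    BVAR (variance of pair means).  Returns 4 statistics x 3 channels."""
    arr = np.asarray(patch3, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    H, W, C = arr.shape
    if H < 3 or W < 3:
        raise ValueError("patch must be at least 3x3")
    if mask is None:
        mask = np.ones((H, W), dtype=bool)
    out = []
    for ch in range(C):
        a_list, b_list = [], []
        for y in range(H - 2):
            for x in range(W - 2):
                if not mask[y:y + 3, x:x + 3].all():
                    continue
                unit = arr[y:y + 3, x:x + 3, ch]
                for (y1, x1), (y2, x2) in _CS_PAIRS:
                    a_list.append(unit[y1, x1])
                    b_list.append(unit[y2, x2])
        if not a_list:
            out.extend([0.0, 0.0, 0.0, 0.0])
            continue
        a = np.array(a_list)
        b = np.array(b_list)
        mu = np.concatenate([a, b]).mean()
        scov = float(((a - mu) * (b - mu)).mean())
        var = float((((a - mu) ** 2 + (b - mu) ** 2) / 2).mean())
        svr = scov / var if var > 1e-12 else 0.0
        wvar = float(((a - b) ** 2 / 2).mean())
        pair_means = (a + b) / 2
        bvar = float(pair_means.var())
        out.extend([scov, svr, wvar, bvar])
    return np.array(out)


# ------------------------------------------------------------------ texton

def make_filter_bank() -> list[np.ndarray]:
    """Small multi-scale Gaussian-derivative bank: Gaussian, x/y first
    derivatives and Laplacian-of-Gaussian at two scales (8 filters)."""
    bank = []
    for sigma in (1.0, 2.0):
        size = int(4 * sigma) * 2 + 1
        ax = np.arange(size) - size // 2
        xx, yy = np.meshgrid(ax, ax)
        g = np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma ** 2))
        g /= g.sum()
        gx = -xx / sigma ** 2 * g
        gy = -yy / sigma ** 2 * g
        log = ((xx ** 2 + yy ** 2 - 2 * sigma ** 2) / sigma ** 4) * g
        bank.extend([g, gx, gy, log])
    return bank


def _filter_responses(patch: np.ndarray,
                      bank: list[np.ndarray]) -> np.ndarray:
    p = np.asarray(patch, dtype=float)
    return np.stack([ndimage.convolve(p, f, mode="reflect").ravel()
                     for f in bank], axis=1)


def fit_texton_model(patches: list[np.ndarray],
                     filter_bank: list[np.ndarray] | None = None,
                     k: int = 4, rng_seed: int = 0) -> TextonModel:
    """K-means over per-pixel filter responses; the cluster centers are
    the textons.  Centers are sorted by first coordinate so the model is
    deterministic given the seed."""
    bank = filter_bank if filter_bank is not None else make_filter_bank()
    resp = np.vstack([_filter_responses(p, bank) for p in patches])
    if np.unique(resp, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct response vectors")
    km = KMeans(n_clusters=k, random_state=rng_seed, n_init=10)
    km.fit(resp)
    centers = km.cluster_centers_[np.argsort(km.cluster_centers_[:, 0])]
    return TextonModel(bank, centers, k)


def texton_histogram(patch: np.ndarray, model: TextonModel,
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Nearest-texton assignment per pixel, normalized k-bin histogram."""
    resp = _filter_responses(patch, model.filter_bank)
    if mask is not None:
        resp = resp[np.asarray(mask, bool).ravel()]
    if resp.shape[0] == 0:
        return np.zeros(model.k)
    d2 = ((resp[:, None, :] - model.textons[None, :, :]) ** 2).sum(-1)
    assign = d2.argmin(1)
    hist = np.bincount(assign, minlength=model.k).astype(float)
    return hist / hist.sum()


# ----------------------------------------------------------- cell pipeline

def lab_channels(rgb: np.ndarray) -> np.ndarray:
    """Lab conversion with L rescaled to [0, 255]; a, b left as-is."""
    lab = rgb2lab(rgb)
    lab[:, :, 0] *= 2.55
    return lab


def cell_descriptor(rgb: np.ndarray, mask: np.ndarray, label: int,
                    model: TextonModel,
                    contour: np.ndarray | None = None,
                    lab: np.ndarray | None = None) -> CellDescriptor:
    """All descriptors for one labeled cell.  Texture statistics are
    computed on the cell's bounding-box patch with pixels outside the mask
    excluded."""
    if lab is None:
        lab = lab_channels(rgb)
    sel = mask == label
    ys, xs = np.nonzero(sel)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    # pad bounding box to at least 3x3 for the 3x3 texture operators
    y1 = max(y1, min(y0 + 3, mask.shape[0]))
    x1 = max(x1, min(x0 + 3, mask.shape[1]))
    cell_mask = sel[y0:y1, x0:x1]
    L = lab[y0:y1, x0:x1, 0]
    scalars = geometry_features(sel, contour)
    scalars.update(intensity_features(lab[ys, xs, 0]))
    scalars.update(glcm_features(L, cell_mask))
    return CellDescriptor(
        scalars=scalars,
        lbp_hist=lbp_features(L, cell_mask),
        tfcm_hist=tfcm_features(L, cell_mask),
        csac_vec=csac_features(lab[y0:y1, x0:x1], cell_mask),
        texton_hist=texton_histogram(L, model, cell_mask),
    )


# ----------------------------------------------------------- aggregation

def _six_stats(values: np.ndarray) -> list[float]:
    """mean, median, population variance and the 3 frequencies of a 3-bin
    histogram spanning the per-patient min-max (all-equal values fall in
    the lowest bin)."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi > lo:
        freq, _ = np.histogram(v, bins=3, range=(lo, hi))
        freq = freq / v.size
    else:
        freq = np.array([1.0, 0.0, 0.0])
    return [float(v.mean()), float(np.median(v)), float(v.var()),
            float(freq[0]), float(freq[1]), float(freq[2])]


def aggregate_patient_vector(cells: list[CellDescriptor],
                             patient_id: str = "") -> pd.Series:
    """Reduce per-cell descriptors to the 166 named patient features."""
    if len(cells) < 2:
        raise ValueError("need at least 2 cells (variances undefined)")
    out: dict[str, float] = {}
    for prefix in _PREFIXES:
        key = _SCALAR_FOR_PREFIX[prefix]
        vals = np.array([c.scalars[key] for c in cells])
        for i, stat in enumerate(_six_stats(vals), start=1):
            out[f"{prefix}{i}"] = stat
    for prefix, attr in (("tfcm", "tfcm_hist"), ("lbp", "lbp_hist")):
        mat = np.stack([getattr(c, attr) for c in cells])   # (n_cells, 8)
        stats = np.concatenate([mat.mean(0), np.median(mat, 0), mat.var(0)])
        for i, s in enumerate(stats, start=1):
            out[f"{prefix}{i}"] = float(s)
    cs = np.stack([c.csac_vec for c in cells])              # (n_cells, 12)
    for i, s in enumerate(np.concatenate([cs.mean(0), cs.var(0)]), start=1):
        out[f"csac{i}"] = float(s)
    tx = np.stack([c.texton_hist for c in cells])
    for i, s in enumerate(tx.mean(0), start=1):
        out[f"t{i}"] = float(s)
    series = pd.Series([out[n] for n in PATIENT_FEATURE_NAMES],
                       index=PATIENT_FEATURE_NAMES, name=patient_id or None)
    return series


def normalize_table(table: pd.DataFrame,
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Per-column z-scores (population SD).  Zero-variance columns map to
    zero and are returned in the flagged list."""
    if len(table) < 2:
        raise ValueError("need at least 2 patients")
    mu = table.mean(axis=0)
    sd = table.std(axis=0, ddof=0)
    flagged = list(table.columns[sd < 1e-12])
    sd_safe = sd.replace(0.0, 1.0)
    sd_safe[sd < 1e-12] = 1.0
    z = (table - mu) / sd_safe
    z[flagged] = 0.0
    return z, flagged
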