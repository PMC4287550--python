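"""Synthetic data generators.

Three generators back the rest of the toolkit so that every stage can be
exercised with known ground truth:

* :func:`synth_cell_image` — H&E-like tiles of textured elliptical nuclei
  (darker than background, optionally touching/overlapping) with exact
  seed coordinates and a label mask;
* :func:`synth_classification_cohort` — two-class feature tables with a
  controlled standardized mean shift on a chosen feature subset;
* :func:`synth_survival_cohort` — right-censored Cox–Weibull cohorts with
  a sparse true coefficient vector.

All generators are pure functions of their spec, including the RNG seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter


class PackingError(RuntimeError):
    """Raised when nuclei cannot be placed under the overlap constraints."""


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of a synthetic nuclei tile.

    Nuclei are rendered darker than the background, as hematoxylin-stained
    nuclei appear against eosin-stained cytoplasm, so image gradients at
    nucleus boundaries point outward and the negative gradient points into
    the nucleus.
    """

    width: int = 256
    height: int = 256
    n_cells: int = 20
    radius_range: tuple[float, float] = (8.0, 12.0)
    eccentricity_range: tuple[float, float] = (1.0, 1.5)
    overlap_fraction: float = 0.0
    fg_intensity: float = 90.0
    bg_intensity: float = 200.0
    texture_amplitude: float = 30.0
    noise_sd: float = 4.0
    rng_seed: int = 0
    #: optional hard floor on center-to-center spacing for non-touching cells
    min_center_distance: float | None = None

    def __post_init__(self) -> None:
        if self.radius_range[0] < 3:
            raise ValueError("minimum radius must be >= 3 pixels")
        if not self.fg_intensity < self.bg_intensity:
            raise ValueError("nuclei must be darker than background")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticSurvivalSpec:
    """Parameters of a right-censored Cox–Weibull survival cohort."""

    n: int = 200
    p: int = 50
    true_beta: tuple[float, ...] = ()
    baseline_shape: float = 1.5
    baseline_scale: float = 365.0
    censor_rate: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if len(self.true_beta) > self.p:
            raise ValueError("true_beta longer than number of covariates")


def _place_centers(spec: SyntheticImageSpec, radii: np.ndarray,
                   rng: np.random.Generator,
                   forced_centers: Sequence[tuple[float, float]] | None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Place nucleus centers; a prefix may be forced by the caller.

    Returns (centers, touching_flags).  The first cell is always free; each
    subsequent cell is a "touching" cell with probability overlap_fraction,
    in which case it is deliberately dropped next to an existing cell at a
    center distance below the sum of radii.
    """
    n = spec.n_cells
    centers = np.zeros((n, 2))
    touching = np.zeros(n, dtype=bool)
    margin = 2.0
    placed = 0
    if forced_centers is not None:
        k = len(forced_centers)
        centers[:k] = np.asarray(forced_centers, dtype=float)
        placed = k
    max_tries = 400 * n
    tries = 0
    while placed < n:
        tries += 1
        if tries > max_tries:
            raise PackingError(
                f"could not place {n} cells of radius <= {radii.max():.1f} "
                f"in a {spec.width}x{spec.height} tile")
        r = radii[placed]
        want_touch = placed > 0 and rng.random() < spec.overlap_fraction
        if want_touch:
            j = rng.integers(placed)
            gap = rng.uniform(0.75, 0.98)  # center dist below sum of radii
            ang = rng.uniform(0, 2 * np.pi)
            d = gap * (r + radii[j])
            c = centers[j] + d * np.array([np.cos(ang), np.sin(ang)])
        else:
            c = np.array([rng.uniform(r + margin, spec.width - r - margin),
                          rng.uniform(r + margin, spec.height - r - margin)])
        if not (r + 1 <= c[0] <= spec.width - r - 1
                and r + 1 <= c[1] <= spec.height - r - 1):
            continue
        if placed > 0:
            dists = np.linalg.norm(centers[:placed] - c, axis=1)
            sums = radii[:placed] + r
            if want_touch:
                # may touch its anchor but must not swallow any nucleus
                if np.any(dists < 0.6 * sums):
                    continue
            else:
                floor = sums + margin
                if spec.min_center_distance is not None:
                    floor = np.maximum(floor, spec.min_center_distance)
                if np.any(dists < floor):
                    continue
        centers[placed] = c
        touching[placed] = want_touch
        placed += 1
    return centers, touching


def synth_cell_image(spec: SyntheticImageSpec,
                     forced_centers: Sequence[tuple[float, float]] | None = None,
                     ) -> tuple[np.ndarray, list[tuple[float, float]], np.ndarray]:
    """Render a synthetic nuclei tile.

    Parameters
    ----------
    spec:
        Geometry, intensity and noise parameters.
    forced_centers:
        Optional explicit centers for the first cells (testing hook, e.g. to
        force a touching pair at a known distance).

    Returns
    -------
    rgb : uint8 array (H, W, 3)
    seeds : list of (x, y) centroids, one per labeled region
    mask : int32 label image (H, W); 0 is background.  Overlapping nuclei
        are resolved to a partition by assigning contested pixels to the
        nearest generating center, so each foreground pixel carries exactly
        one label.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_cells
    radii = rng.uniform(*spec.radius_range, size=n)
    eccs = rng.uniform(*spec.eccentricity_range, size=n)
    thetas = rng.uniform(0, np.pi, size=n)
    centers, _ = _place_centers(spec, radii, rng, forced_centers)

    H, W = spec.height, spec.width
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    mask = np.zeros((H, W), dtype=np.int32)
    # squared normalized ellipse distance per cell; nearest-center tie-break
    best_center_d2 = np.full((H, W), np.inf)
    for i in range(n):
        a = radii[i] * np.sqrt(eccs[i])     # semi-major
        b = radii[i] / np.sqrt(eccs[i])     # semi-minor
        ct, st = np.cos(thetas[i]), np.sin(thetas[i])
        dx = xx - centers[i, 0]
        dy = yy - centers[i, 1]
        u = (dx * ct + dy * st) / a
        v = (-dx * st + dy * ct) / b
        inside = u * u + v * v <= 1.0
        d2 = dx * dx + dy * dy
        take = inside & (d2 < best_center_d2)
        mask[take] = i + 1
        best_center_d2[take] = d2[take]

    fg = mask > 0
    lum = np.full((H, W), spec.bg_intensity, dtype=float)
    texture = gaussian_filter(rng.standard_normal((H, W)), sigma=1.5)
    sd = texture.std()
    if sd > 0:
        texture /= sd
    mult = 1.0 + (spec.texture_amplitude / 255.0) * texture
    lum[fg] = spec.fg_intensity * mult[fg]
    lum = gaussian_filter(lum, sigma=1.0)  # soften boundaries ~1 px
    lum += spec.noise_sd * rng.standard_normal((H, W))

    # eosin-pink background / hematoxylin-purple nuclei channel balance
    weights = np.array([0.88, 0.72, 0.96])
    rgb = lum[:, :, None] * weights[None, None, :]
    rgb += 0.5 * rng.standard_normal((H, W, 3))
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    seeds: list[tuple[float, float]] = []
    labels_present = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(mask == lab)
        if xs.size == 0:
            continue
        labels_present.append(lab)
        seeds.append((float(xs.mean()), float(ys.mean())))
    # relabel compactly in case a nucleus was fully claimed by neighbors
    if len(labels_present) < n:
        relab = np.zeros(n + 1, dtype=np.int32)
        for new, old in enumerate(labels_present, start=1):
            relab[old] = new
        mask = relab[mask]
    return rgb, seeds, mask


def synth_survival_cohort(spec: SyntheticSurvivalSpec) -> pd.DataFrame:
    """Draw a right-censored cohort from a Cox–Weibull model.

    Event times follow the proportional-hazards construction
    ``T = scale * (-log U / exp(beta' x))**(1/shape)`` with ``x`` standard
    normal, so the model's hazard ratios hold exactly by construction.
    Censoring times are drawn from the baseline Weibull with its scale
    calibrated by bisection on the realized sample so that the achieved
    censoring fraction matches ``censor_rate``.

    Returns a DataFrame with columns ``time``, ``event`` and ``x1..xp``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, p = spec.n, spec.p
    beta = np.zeros(p)
    beta[: len(spec.true_beta)] = spec.true_beta
    X = rng.standard_normal((n, p))
    eta = X @ beta
    u = rng.uniform(size=n)
    T = spec.baseline_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / spec.baseline_shape)

    if spec.censor_rate == 0.0:
        time, event = T, np.ones(n, dtype=int)
    else:
        c0 = spec.baseline_scale * (-np.log(rng.uniform(size=n))) ** (
            1.0 / spec.baseline_shape)

        def censored_frac(scale_mult: float) -> float:
            return float(np.mean(scale_mult * c0 < T))

        lo, hi = 1e-6, 1e6
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if censored_frac(mid) > spec.censor_rate:
                lo = mid
            else:
                hi = mid
        C = np.sqrt(lo * hi) * c0
        event = (T <= C).astype(int)
        time = np.minimum(T, C)

    df = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(p)])
    df.insert(0, "event", event)
    df.insert(0, "time", time)
    return df


def synth_classification_cohort(n_per_class: int, p: int,
                                shifted_idx: Sequence[int],
                                effect: float,
                                rng_seed: int = 0,
                                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-class Gaussian feature cohort with a controlled mean shift.

    Features listed in ``shifted_idx`` (0-based) differ between the two
    classes by ``effect`` standard deviations; the remaining features are
    exchangeable between classes.  Class labels are ``"AC"`` and ``"SCC"``.
    """
    if any(j < 0 or j >= p for j in shifted_idx):
        raise ValueError("shifted_idx out of range")
    rng = np.random.default_rng(rng_seed)
    X = rng.standard_normal((2 * n_per_class, p))
    labels = np.array(["AC"] * n_per_class + ["SCC"] * n_per_class)
    for j in shifted_idx:
        X[:n_per_class, j] += effect / 2.0
        X[n_per_class:, j] -= effect / 2.0
    table = pd.DataFrame(X, columns=[f"f{j + 1}" for j in range(p)])
    return table, labels
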