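"""Mitotic-timing classification of mosaic variants from their VAFs.

A variant arising at the k-th postzygotic cell division is expected at VAF
2^-(k+1): 0.25 for the first mitosis, 0.125 for the second, with 0.5 the
constitutional heterozygous (germline) expectation. Read sampling spreads
each component into an approximately binomial lobe, so the boundaries
between adjacent components are taken where their densities cross.

Each component's VAF density is modeled with the continuous extension of
the binomial distribution (Ilienko's continuous binomial), whose CDF on
support x in [0, n+1] is the regularized incomplete beta
``I_{1-p}(n + 1 - x, x)``; at integer x = k+1 this equals the discrete
binomial CDF at k. The VAF axis is x/n. Boundaries are estimated the
Monte-Carlo way: 10,000 draws per component, Gaussian kernel density
estimates with a pooled Silverman bandwidth, crossing point on a common
grid — with an exact dense-grid analytic crossing available as an oracle.

The published bins are available as a preset: second mitosis
9.55-18.69%, first mitosis 18.7-37.41%, germline 37.41-62.59%. Bin edges
are half-open, lower-inclusive; VAFs in the printed gap (18.69%, 18.7%)
fall to the upper bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

SUB_THRESHOLD = "sub-threshold"
SECOND_MITOSIS = "second-mitosis"
FIRST_MITOSIS = "first-mitosis"
GERMLINE = "germline"
ABOVE_GERMLINE = "above-germline"

#: Published VAF bins with their printed edges: (label, low, high).
PUBLISHED_BINS: tuple[tuple[str, float, float], ...] = (
    (SECOND_MITOSIS, 0.0955, 0.1869),
    (FIRST_MITOSIS, 0.187, 0.3741),
    (GERMLINE, 0.3741, 0.6259),
)

DEFAULT_COMPONENTS: tuple[tuple[str, float], ...] = (
    (GERMLINE, 0.5),
    (FIRST_MITOSIS, 0.25),
    (SECOND_MITOSIS, 0.125),
    ("third-division", 0.0625),
)


class BoundaryEstimationError(RuntimeError):
    pass


def continuous_binomial_cdf(x, p: float, n: int):
    """CDF of the continuous binomial on support [0, n+1] (count axis)."""
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if n < 1:
        raise ValueError("n must be >= 1")
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    inside = (x > 0) & (x < n + 1)
    out[x <= 0] = 0.0
    out[x >= n + 1] = 1.0
    xi = x[inside]
    out[inside] = special.betainc(n + 1 - xi, xi, 1 - p)
    return out if out.ndim else float(out)


def continuous_binomial_density(x, p: float, n: int, _h: float = 1e-5):
    """Density of the continuous binomial on the VAF axis.

    ``x`` is a VAF (alt fraction); the count-axis support [0, n+1] maps to
    VAF support [0, (n+1)/n]. Computed as a central difference of the CDF.
    Integrates to 1 over the support (checked by quadrature in the tests).
    """
    x = np.asarray(x, dtype=float)
    t = x * n
    lo = np.clip(t - _h, 0.0, n + 1.0)
    hi = np.clip(t + _h, 0.0, n + 1.0)
    dens_t = (continuous_binomial_cdf(hi, p, n)
              - continuous_binomial_cdf(lo, p, n)) / np.maximum(hi - lo, 1e-300)
    dens_t = np.where((t < 0) | (t > n + 1), 0.0, dens_t)
    out = dens_t * n  # change of variable t = x*n
    return out if out.ndim else float(out)


def sample_continuous_binomial(p: float, n: int, size: int,
                               rng: np.random.Generator,
                               grid_points: int = 4096) -> np.ndarray:
    """Draw VAF samples by inverse-CDF interpolation on a dense grid."""
    grid = np.linspace(0.0, n + 1.0, grid_points)
    cdf = continuous_binomial_cdf(grid, p, n)
    cdf, idx = np.unique(cdf, return_index=True)
    grid = grid[idx]
    u = rng.uniform(size=size)
    return np.interp(u, cdf, grid) / n


def silverman_bandwidth(sample: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a 1-d Gaussian KDE."""
    m = sample.size
    sd = float(np.std(sample, ddof=1))
    iqr = float(np.subtract(*np.percentile(sample, [75, 25])))
    a = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * a * m ** (-0.2)


def _kde_on_grid(sample: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    z = (grid[:, None] - sample[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (sample.size * h * np.sqrt(2 * np.pi))


@dataclass
class TimingModel:
    """Ordered VAF components and the boundaries between them."""

    components: tuple[tuple[str, float], ...] = DEFAULT_COMPONENTS
    depth: int = 50
    n_draws: int = 10_000
    seed: int = 0
    boundaries: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        fracs = [p for _, p in self.components]
        if any(b >= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("component VAFs must be strictly decreasing")
        if self.boundaries:
            self._check_interleaving()

    def _check_interleaving(self) -> None:
        fracs = [p for _, p in self.components]
        for i, b in enumerate(self.boundaries):
            if not fracs[i] > b > fracs[i + 1]:
                raise ValueError(
                    f"boundary {b} does not interleave components "
                    f"{fracs[i]} and {fracs[i + 1]}")

    def bins(self) -> tuple[tuple[str, float, float], ...]:
        """Lower-inclusive (label, low, high) bins from the boundaries."""
        if not self.boundaries:
            raise ValueError("boundaries not estimated yet")
        cuts = list(self.boundaries)  # decreasing
        out = []
        labels = [lab for lab, _ in self.components]
        # highest component spans (first boundary, upper germline edge)
        uppers = [min(2 * self.components[0][1] - cuts[0], 1.0)] + cuts[:-1]
        for label, upper, lower in zip(labels[:-1], uppers, cuts):
            out.append((label, lower, upper))
        return tuple(reversed(out))


def _pair_boundary_mc(p_hi: float, p_lo: float, depth: int, n_draws: int,
                      rng: np.random.Generator) -> float:
    s_hi = sample_continuous_binomial(p_hi, depth, n_draws, rng)
    s_lo = sample_continuous_binomial(p_lo, depth, n_draws, rng)
    h = silverman_bandwidth(np.concatenate([s_hi, s_lo]))
    grid = np.linspace(p_lo, p_hi, 801)
    diff = _kde_on_grid(s_hi, grid, h) - _kde_on_grid(s_lo, grid, h)
    return _closest_crossing(grid, diff, (p_lo + p_hi) / 2)


def _closest_crossing(grid: np.ndarray, diff: np.ndarray,
                      midpoint: float) -> float:
    sign_change = np.nonzero(np.diff(np.signbit(diff)))[0]
    if sign_change.size == 0:
        raise BoundaryEstimationError(
            "densities do not cross between the component means; "
            "increase n_draws or use the analytic fallback")
    crossings = []
    for i in sign_change:
        x0, x1, y0, y1 = grid[i], grid[i + 1], diff[i], diff[i + 1]
        crossings.append(x0 if y1 == y0 else x0 - y0 * (x1 - x0) / (y1 - y0))
    return min(crossings, key=lambda c: abs(c - midpoint))


def estimate_boundaries(model: TimingModel) -> TimingModel:
    """Monte-Carlo boundary estimation between each adjacent component pair.

    Deterministic for a fixed ``model.seed``; returns the model with
    ``boundaries`` filled (strictly decreasing, interleaving the component
    expectations).
    """
    rng = np.random.default_rng(model.seed)
    boundaries = []
    for (_, p_hi), (_, p_lo) in zip(model.components, model.components[1:]):
        if p_hi == p_lo:
            raise BoundaryEstimationError("identical adjacent components")
        boundaries.append(
            _pair_boundary_mc(p_hi, p_lo, model.depth, model.n_draws, rng))
    model.boundaries = boundaries
    model._check_interleaving()
    return model


def analytic_boundaries(model: TimingModel, grid_points: int = 20_001
                        ) -> list[float]:
    """Exact dense-grid crossings of the analytic densities (sampling-free
    oracle for the Monte-Carlo estimate)."""
    out = []
    for (_, p_hi), (_, p_lo) in zip(model.components, model.components[1:]):
        grid = np.linspace(p_lo, p_hi, grid_points)
        diff = (continuous_binomial_density(grid, p_hi, model.depth)
                - continuous_binomial_density(grid, p_lo, model.depth))
        out.append(_closest_crossing(grid, diff, (p_lo + p_hi) / 2))
    return out


def classify_timing(vaf: float,
                    bins: tuple[tuple[str, float, float], ...] = PUBLISHED_BINS,
                    ) -> str:
    """Assign a VAF to a timing bin.

    Bins are lower-inclusive: where two bins share an edge the edge belongs
    to the upper bin; values in a printed gap (e.g. (18.69%, 18.7%)) go to
    the upper bin. Below the lowest bin -> "sub-threshold"; above the
    highest -> "above-germline".
    """
    ordered = sorted(bins, key=lambda b: b[1])
    if vaf < ordered[0][1]:
        return SUB_THRESHOLD
    for i, (label, low, high) in enumerate(ordered):
        if vaf < low:  # fell in a printed gap below this bin
            return label
        if vaf <= high:
            next_low = ordered[i + 1][1] if i + 1 < len(ordered) else None
            if next_low is not None and vaf == high == next_low:
                continue  # shared edge belongs to the upper bin
            return label
    return ABOVE_GERMLINE


BIN_ORDER = (SECOND_MITOSIS, FIRST_MITOSIS, GERMLINE, SUB_THRESHOLD,
             ABOVE_GERMLINE)


def timing_table(candidates,
                 bins: tuple[tuple[str, float, float], ...] = PUBLISHED_BINS,
                 ) -> pd.DataFrame:
    """Tabulate candidates per timing bin, split SNV/indel.

    ``candidates`` is an iterable of objects with ``vaf`` and
    ``variant_class`` attributes (or (vaf, variant_class) pairs). Rows
    follow the published layout (second mitosis, first mitosis, germline)
    followed by the sub-threshold and above-germline buckets; totals sum to
    the input count.
    """
    counts = {label: {"SNV": 0, "indel": 0} for label in BIN_ORDER}
    ranges = {label: f"{low * 100:g}% - {high * 100:g}%"
              for label, low, high in bins}
    ranges.setdefault(SUB_THRESHOLD, f"< {min(b[1] for b in bins) * 100:g}%")
    ranges.setdefault(ABOVE_GERMLINE, f"> {max(b[2] for b in bins) * 100:g}%")
    for cand in candidates:
        if isinstance(cand, tuple):
            vaf, variant_class = cand
        else:
            vaf, variant_class = cand.vaf, cand.variant_class
        label = classify_timing(vaf, bins)
        counts[label][variant_class] += 1
    rows = []
    for label in BIN_ORDER:
        snv, indel = counts[label]["SNV"], counts[label]["indel"]
        rows.append({"bin": label, "vaf_range": ranges.get(label, ""),
                     "snv": snv, "indel": indel, "total": snv + indel})
    return pd.DataFrame(rows, columns=["bin", "vaf_range", "snv", "indel",
                                       "total"])


def assign_origin_bins(candidates,
                       bins: tuple[tuple[str, float, float], ...] = PUBLISHED_BINS,
                       ) -> None:
    """Attach ``timing_bin`` and ``origin_bin`` (germline/somatic) to each
    candidate in place; mosaic bins (and sub-threshold) count as somatic."""
    for cand in candidates:
        label = classify_timing(cand.vaf, bins)
        cand.timing_bin = label
        cand.origin_bin = ("germline" if label in (GERMLINE, ABOVE_GERMLINE)
                           else "somatic")


def plot_vaf_density(vafs, model: TimingModel, path: str) -> None:
    """Histogram of candidate VAFs with the per-component analytic density
    curves overlaid (descriptive plot of the bimodal structure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vafs = np.asarray(list(vafs), dtype=float)
    fig, ax = plt.subplots(figsize=(7, 4))
    if vafs.size:
        ax.hist(vafs, bins=np.arange(0, 1.02, 0.02), density=True,
                alpha=0.5, color="firebrick", label="candidate VAFs")
    grid = np.linspace(0.001, 1.0, 500)
    for label, p in model.components:
        ax.plot(grid, continuous_binomial_density(grid, p, model.depth),
                lw=1.2, label=f"{label} (p={p})")
    for b in model.boundaries:
        ax.axvline(b, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("VAF")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
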