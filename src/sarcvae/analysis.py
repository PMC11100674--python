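"""Diagnostics and workflows on posterior sample sets.

Probability-probability calibration against a validation set, corner-style
density summaries with joint-peak extraction, the signed two-sample
Kolmogorov-Smirnov comparison between inferred conditions, and the
hybrid-twitch / thick-filament-intervention procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .cvae import CVAEPosterior, PosteriorSampleSet
from .dataset import TrainingDataset, standardize_trace
from .kinetics import RateFactors
from .params import FACTOR_NAMES, THICK_FACTOR_NAMES, ModelConfig

__all__ = ["PPCurve", "pp_curve", "corner_summary", "signed_ks",
           "make_hybrid_factors", "intervention_inference", "CornerSummary"]


@dataclass
class PPCurve:
    """Claimed credible level vs empirical coverage, per factor.

    ``levels`` and ``coverage[:, k]`` both live in [0, 1] and are
    non-decreasing; the diagonal is perfect calibration, points above it
    under-confidence, points below over-confidence.
    """

    levels: np.ndarray              # (L,)
    coverage: np.ndarray            # (L, n_factors)
    names: tuple[str, ...]
    cdf_values: np.ndarray          # (n_records, n_factors) CDF at truth

    def max_deviation(self) -> np.ndarray:
        """Per-factor sup-distance from the diagonal."""
        return np.max(np.abs(self.coverage - self.levels[:, None]), axis=0)


def pp_curve_from_cdf(cdf_values: np.ndarray, names,
                      n_levels: int = 101) -> PPCurve:
    """Build the PP curve from per-record marginal CDF values at the truth.

    For a perfectly calibrated posterior the CDF values are U(0,1), so
    their empirical CDF traces the diagonal.
    """
    cdf_values = np.atleast_2d(np.asarray(cdf_values, dtype=float))
    levels = np.linspace(0.0, 1.0, n_levels)
    coverage = (cdf_values[None, :, :] <= levels[:, None, None]).mean(axis=1)
    coverage[0] = 0.0
    coverage[-1] = 1.0
    return PPCurve(levels=levels, coverage=coverage, names=tuple(names),
                   cdf_values=cdf_values)


def pp_curve(model: CVAEPosterior, validation_traces: np.ndarray,
             validation_factors: np.ndarray, names=FACTOR_NAMES,
             n_samples: int = 1000, seed: int | tuple = 0,
             rng_ties: np.random.Generator | None = None) -> PPCurve:
    """Probability-probability calibration over a validation set.

    For each record, the fraction of posterior samples strictly below the
    true factor gives the marginal CDF value at the truth (ties broken at
    random — measure zero for continuous samples); the PP curve is the
    empirical CDF of those values across records.
    """
    validation_traces = np.atleast_2d(validation_traces)
    validation_factors = np.atleast_2d(validation_factors)
    if validation_traces.shape[0] == 0:
        raise ValueError("validation set is empty")
    rng_ties = rng_ties or np.random.default_rng(0)
    base = (seed,) if isinstance(seed, int) else tuple(seed)
    rows = []
    for i, (x, yt) in enumerate(zip(validation_traces, validation_factors)):
        s = model.sample_posterior(x, n=n_samples, seed=base + (i,))
        below = (s < yt[None, :]).mean(axis=0)
        ties = (s == yt[None, :]).mean(axis=0)
        rows.append(below + ties * rng_ties.random(s.shape[1]))
    return pp_curve_from_cdf(np.array(rows), names)


# ---------------------------------------------------------------------------
# corner summaries

@dataclass
class CornerSummary:
    """KDE summaries of a posterior sample set on log10 axes."""

    names: tuple[str, ...]
    joint_peak: np.ndarray            # (n_factors,) log10 factors
    marginal_modes: np.ndarray        # (n_factors,)
    marginal_grids: list              # [(grid, density)] per factor
    pair_densities: dict              # (i, j) -> (gx, gy, density)
    axis_limits: tuple[float, float] = (-1.0, 2.0)

    def peak_factors(self, all_names=FACTOR_NAMES,
                     base: RateFactors | None = None) -> RateFactors:
        """The most probable factor combination as a RateFactors vector."""
        fac = base or RateFactors()
        return fac.replace(**{n: float(10.0 ** v)
                              for n, v in zip(self.names, self.joint_peak)})


def corner_summary(samples: PosteriorSampleSet, grid_size: int = 60,
                   pair_grid: int = 40) -> CornerSummary:
    """1-D marginals, pairwise 2-D densities, and the joint KDE peak.

    The joint peak is the sample maximizing the Gaussian KDE (Scott's rule
    on log10 samples), refined by local ascent on the KDE surface; this is
    the "most probable value" reported by the inference workflows.
    Degenerate (zero-variance) dimensions are carried as point masses.
    """
    x = samples.samples
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    n, d = x.shape
    lo, hi = samples.prior_bounds
    var = x.var(axis=0)
    live = var > 1e-12

    # joint peak: KDE over non-degenerate dims, evaluated at the samples
    if live.sum() >= 1:
        kde = gaussian_kde(x[:, live].T)
        dens = kde(x[:, live].T)
        peak = x[int(np.argmax(dens))].copy()
        # local ascent refinement
        step = x[:, live].std(axis=0) * 0.25
        cur = peak[live].copy()
        best = kde(cur[:, None])[0]
        for _ in range(40):
            moved = False
            for k in range(live.sum()):
                for sgn in (+1.0, -1.0):
                    trial = cur.copy()
                    trial[k] += sgn * step[k]
                    val = kde(trial[:, None])[0]
                    if val > best:
                        best, cur, moved = val, trial, True
            if not moved:
                step *= 0.5
                if np.all(step < 1e-4):
                    break
        peak[live] = cur
    else:
        peak = x[0].copy()

    marg_modes = np.empty(d)
    grids = []
    for k in range(d):
        g = np.linspace(lo, hi, grid_size)
        if var[k] > 1e-12:
            mk = gaussian_kde(x[:, k])
            dk = mk(g)
            marg_modes[k] = g[int(np.argmax(dk))]
        else:
            dk = np.zeros(grid_size)
            dk[int(np.clip((x[0, k] - lo) / (hi - lo) * (grid_size - 1),
                           0, grid_size - 1))] = 1.0
            marg_modes[k] = x[0, k]
        grids.append((g, dk))

    pairs = {}
    for i in range(d):
        for j in range(i + 1, d):
            gx = np.linspace(lo, hi, pair_grid)
            gy = np.linspace(lo, hi, pair_grid)
            if var[i] > 1e-12 and var[j] > 1e-12:
                kde2 = gaussian_kde(x[:, [i, j]].T)
                xx, yy = np.meshgrid(gx, gy, indexing="ij")
                zz = kde2(np.vstack([xx.ravel(), yy.ravel()])).reshape(
                    pair_grid, pair_grid)
            else:
                zz = np.zeros((pair_grid, pair_grid))
            pairs[(i, j)] = (gx, gy, zz)
    return CornerSummary(names=samples.names, joint_peak=peak,
                         marginal_modes=marg_modes, marginal_grids=grids,
                         pair_densities=pairs,
                         axis_limits=samples.prior_bounds)


def plot_corner(summary: CornerSummary, samples: PosteriorSampleSet,
                path: str, truth: np.ndarray | None = None) -> None:
    """Corner plot (pairwise densities + marginals) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    d = len(summary.names)
    fig, axes = plt.subplots(d, d, figsize=(2.2 * d, 2.2 * d),
                             squeeze=False)
    lo, hi = summary.axis_limits
    for i in range(d):
        for j in range(d):
            ax = axes[i][j]
            if j > i:
                ax.axis("off")
                continue
            if i == j:
                g, dk = summary.marginal_grids[i]
                ax.plot(g, dk, lw=1)
                ax.axvline(summary.joint_peak[i], color="g", lw=1)
                if truth is not None:
                    ax.axvline(truth[i], color="r", lw=1)
            else:
                gx, gy, zz = summary.pair_densities[(j, i)]
                ax.contourf(gx, gy, zz.T, levels=8, cmap="Blues")
                ax.plot(summary.joint_peak[j], summary.joint_peak[i], "go",
                        ms=4)
                if truth is not None:
                    ax.plot(truth[j], truth[i], "ro", ms=4)
                ax.set_ylim(lo, hi)
            ax.set_xlim(lo, hi)
            if i == d - 1:
                ax.set_xlabel(f"log10 {summary.names[j]}")
            if j == 0 and i > 0:
                ax.set_ylabel(f"log10 {summary.names[i]}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# signed Kolmogorov-Smirnov comparison

def signed_ks(samples_a: np.ndarray, samples_b: np.ndarray) -> np.ndarray:
    """Per-factor signed two-sample KS statistic, reference = ``a``.

    The magnitude is the classical sup-distance between the two empirical
    CDFs; the sign is negative when the reference (control) CDF is smaller
    at the maximizing point (i.e. the control distribution carries more
    mass at larger values there).
    """
    a = np.atleast_2d(np.asarray(samples_a, dtype=float))
    b = np.atleast_2d(np.asarray(samples_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("sample sets must be non-empty")
    out = np.empty(a.shape[1])
    for k in range(a.shape[1]):
        xa = np.sort(a[:, k])
        xb = np.sort(b[:, k])
        grid = np.concatenate([xa, xb])
        ca = np.searchsorted(xa, grid, side="right") / xa.size
        cb = np.searchsorted(xb, grid, side="right") / xb.size
        diff = ca - cb
        i = int(np.argmax(np.abs(diff)))
        out[k] = abs(diff[i]) * (-1.0 if diff[i] < 0 else 1.0)
    return out


# ---------------------------------------------------------------------------
# hybrid twitch and thick-filament intervention

def make_hybrid_factors(control_peak: RateFactors, variant_peak: RateFactors,
                        swap_names: tuple[str, ...] = ("rt12", "rt41"),
                        ) -> RateFactors:
    """Control factors with the calcium-affinity coordinates of the variant.

    Default swap set is the two thin-filament calcium-affinity rates; the
    result simulated forward is the "hybrid" twitch.
    """
    for n in swap_names:
        if n not in FACTOR_NAMES:
            raise KeyError(f"unknown rate factor {n!r}")
    return control_peak.replace(**{n: getattr(variant_peak, n)
                                   for n in swap_names})


def intervention_inference(model: CVAEPosterior, dataset: TrainingDataset,
                           target_trace: np.ndarray,
                           hybrid: RateFactors,
                           thick_names: tuple[str, ...] = THICK_FACTOR_NAMES,
                           n: int = 5000, seed: int | tuple = 0,
                           config: ModelConfig | None = None,
                           simulate_peak: bool = True):
    """Posterior over thick-filament factors that best recover a target.

    ``model``/``dataset`` must come from a reduced-dimension corpus whose
    frozen factors are the hybrid's thin-filament values; the target is the
    (control) twitch to recover.  Returns ``(PosteriorSampleSet,
    peak RateFactors, intervention TwitchTrace or None)``.
    """
    if tuple(dataset.varied) != tuple(thick_names):
        raise ValueError("dataset varied-factor set does not match the "
                         "requested thick-filament names")
    for name, value in dataset.frozen.items():
        if abs(np.log10(getattr(hybrid, name) / value)) > 1e-9:
            raise ValueError(f"frozen factor {name} mismatches the hybrid")
    x = standardize_trace(target_trace, dataset)
    unit = model.sample_posterior(x, n=n, seed=seed)
    log10 = dataset.unscale_factors(unit)
    samples = PosteriorSampleSet(samples=log10, names=tuple(thick_names),
                                 target_id="intervention-target",
                                 prior_bounds=dataset.bounds)
    summary = corner_summary(samples)
    peak = summary.peak_factors(base=hybrid)
    trace = None
    if simulate_peak and config is not None:
        from .simulate import average_replicates
        trace = average_replicates(peak, config, n=20, seed=seed)
    return samples, peak, trace
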