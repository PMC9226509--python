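"""Ensemble FRET histograms and unconstrained multi-Gaussian mixture fits.

Histograms pool a fixed number of frames per molecule (default 21, the
short-movie convention) and are normalized to unit area on [-0.1, 1.2].
Mixtures are fitted to the binned density by least squares with
unconstrained peak positions from seeded multi-start initialization; the
component count is selected by BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .traceproc import FretTrace

HIST_RANGE = (-0.1, 1.2)
FRAMES_PER_MOLECULE = 21
SD_FLOOR = 0.01


@dataclass
class FretHistogram:
    bin_edges: np.ndarray
    densities: np.ndarray
    n_molecules: int
    frames_per_molecule: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)


@dataclass
class MixtureFit:
    K: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bic: float
    converged: bool
    rss: float = math.nan

    @property
    def dominant(self) -> int:
        """Index of the highest-weight component."""
        return int(np.argmax(self.weights))

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        out = np.zeros_like(x)
        for mu, sd, w in zip(self.means, self.sds, self.weights):
            out += w * np.exp(-0.5 * ((x - mu) / sd) ** 2) / \
                (sd * math.sqrt(2 * math.pi))
        return out


def build_histogram(fret_traces: Iterable[FretTrace],
                    frames_per_molecule: int = FRAMES_PER_MOLECULE,
                    bins: int = 65,
                    window: Optional[tuple] = None) -> FretHistogram:
    """Pool the first ``frames_per_molecule`` samples per molecule (inside
    ``window``, if given) and bin to a unit-area density on [-0.1, 1.2]."""
    pool = []
    n_mol = 0
    for tr in fret_traces:
        if tr.donor_only or len(tr) == 0:
            continue
        E = tr.E
        if window is not None:
            sel = (tr.time_s >= window[0]) & (tr.time_s < window[1])
            E = E[sel]
        if len(E) == 0:
            continue
        pool.append(E[:frames_per_molecule])
        n_mol += 1
    if not pool:
        raise ValueError("empty sample pool")
    samples = np.concatenate(pool)
    dens, edges = np.histogram(samples, bins=bins, range=HIST_RANGE,
                               density=True)
    return FretHistogram(bin_edges=edges, densities=dens, n_molecules=n_mol,
                         frames_per_molecule=frames_per_molecule)


def _fit_k(x: np.ndarray, y: np.ndarray, K: int, starts: int,
           rng: np.random.Generator):
    """Best least-squares K-Gaussian fit over seeded multi-starts."""
    from scipy.optimize import least_squares

    span = (x.min(), x.max())
    best = None
    mass = np.clip(y, 0, None)
    mass = mass / mass.sum() if mass.sum() > 0 else np.full_like(y, 1 / len(y))
    mean0 = float(np.sum(x * mass))

    for s in range(starts):
        if s == 0:
            # quantile-spaced means from the observed density
            q = np.cumsum(mass)
            mus = np.interp((np.arange(K) + 0.5) / K, q, x)
        else:
            mus = rng.uniform(mean0 - 0.3, mean0 + 0.3, K)
        sds = np.full(K, 0.05)
        amps = np.full(K, max(y.max(), 1e-3) / K)
        p0 = np.concatenate([mus, np.log(sds), np.log(amps)])

        def resid(p):
            mu = p[:K]
            sd = np.exp(np.clip(p[K:2 * K], -10, 3)) + SD_FLOOR
            a = np.exp(np.clip(p[2 * K:], -30, 30))
            model = np.zeros_like(x)
            for m_, s_, a_ in zip(mu, sd, a):
                model += a_ * np.exp(-0.5 * ((x - m_) / s_) ** 2)
            return model - y

        try:
            sol = least_squares(resid, p0, method="lm", max_nfev=20000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x, sol.success)
    if best is None:
        return None
    rss, p, ok = best
    mu = p[:K]
    sd = np.exp(np.clip(p[K:2 * K], -10, 3)) + SD_FLOOR
    a = np.exp(np.clip(p[2 * K:], -30, 30))
    inside = (mu > span[0] - 0.2) & (mu < span[1] + 0.2)
    if not inside.all():
        ok = False
    # component mass -> weights (area of each Gaussian)
    area = a * sd * math.sqrt(2 * math.pi)
    if area.sum() <= 0:
        return None
    w = area / area.sum()
    order = np.argsort(mu)
    return rss, mu[order], sd[order], w[order], bool(ok)


def fit_mixture(hist: FretHistogram, K_max: int = 3, starts: int = 5,
                seed: int = 0) -> MixtureFit:
    """Fit K = 1..K_max Gaussian mixtures to the binned density and select
    K by BIC; components are reported sorted by mean."""
    if not 1 <= K_max <= 5:
        raise ValueError("K_max must lie in [1, 5]")
    x = hist.centers
    y = hist.densities
    n = len(x)
    rng = np.random.default_rng(seed)
    best: Optional[MixtureFit] = None
    any_ok = False
    for K in range(1, K_max + 1):
        out = _fit_k(x, y, K, starts, rng)
        if out is None:
            continue
        rss, mu, sd, w, ok = out
        any_ok = any_ok or ok
        bic = n * math.log(max(rss / n, 1e-300)) + (3 * K) * math.log(n)
        fit = MixtureFit(K=K, means=mu, sds=sd, weights=w, bic=bic,
                         converged=ok, rss=rss)
        # guard against spike-splitting: a higher K only wins if its
        # components are genuinely distinct peaks (separated by at least
        # twice the broader width) with appreciable mass
        distinct = all(mu[i + 1] - mu[i] > 2 * max(sd[i], sd[i + 1], 0.02)
                       for i in range(K - 1))
        substantial = bool(np.all(w > 0.02))
        if best is None or (bic < best.bic and distinct and substantial):
            best = fit
    if best is None or not any_ok:
        raise RuntimeError(
            "mixture fit failed to converge for any K "
            f"(K_max={K_max}, n_bins={n}, density_max={y.max():.3g})")
    return best


def bound_fraction(obj: Union[FretHistogram, MixtureFit],
                   threshold: float) -> float:
    """Probability mass below a FRET threshold (histogram integral or
    mixture CDF)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if isinstance(obj, FretHistogram):
        below = np.clip((threshold - obj.bin_edges[:-1]) / obj.widths, 0, 1)
        return float(np.sum(obj.densities * obj.widths * below))
    from scipy.stats import norm

    return float(np.sum(obj.weights *
                        norm.cdf(threshold, obj.means, obj.sds)))
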