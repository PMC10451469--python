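"""Particle-swarm search over the VMD hyperparameters (alpha, K).

The fitness of a candidate decomposition is the "maximum
cross-correlation" (MCC) statistic: every mode's Pearson correlation
R_i with the input signal is computed, and

    F = mean(R_i) / sample_std(R_i)            (std with n-1 divisor)

is maximized — decompositions whose modes all correlate with the signal
comparably and strongly carry the fewest artefact modes.  A canonical
global-best PSO flies particles through the (alpha, K) box; K is kept
continuous during flight and rounded to the nearest integer when a
particle is evaluated (standard mixed-integer handling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import SlowTimeSignal
from .vmd import IMFSet, VMDParams, vmd_decompose

__all__ = ["PSOConfig", "FitnessReport", "imf_correlations",
           "mcc_fitness", "evaluate_params", "pso_optimize"]

#: Fitness assigned when the mode correlations have zero spread
#: (mean/std would diverge); any finite decomposition beats noise.
ZERO_STD_FITNESS_CAP = 1e9


@dataclass(frozen=True)
class PSOConfig:
    """Swarm setup; default search box follows common VMD practice."""

    alpha_range: tuple[float, float] = (200.0, 2000.0)
    K_range: tuple[int, int] = (2, 8)
    n_particles: int = 20
    n_iters: int = 30
    inertia: tuple[float, float] = (0.9, 0.4)  # linear schedule start -> end
    c1: float = 2.0
    c2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_range[0] > self.alpha_range[1]:
            raise ValueError("empty alpha range")
        if self.K_range[0] > self.K_range[1]:
            raise ValueError("empty K range")
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")


@dataclass
class FitnessReport:
    """Per-mode correlations and the MCC fitness they produce."""

    correlations: np.ndarray
    mean_corr: float
    fitness: float
    degenerate: bool = False  # True when the zero-variance guard fired


def imf_correlations(signal: SlowTimeSignal, imfs: IMFSet) -> np.ndarray:
    """Pearson correlation of each mode with the original signal.

    A zero-variance mode (or signal) yields a correlation of 0 for that
    entry rather than NaN.
    """
    s = np.asarray(signal.values, dtype=float)
    if imfs.modes.shape[1] != s.size:
        raise ValueError("mode length does not match signal length")
    s_c = s - s.mean()
    s_norm = np.sqrt((s_c**2).sum())
    out = np.zeros(imfs.K)
    for i, mode in enumerate(imfs.modes):
        m_c = mode - mode.mean()
        m_norm = np.sqrt((m_c**2).sum())
        if s_norm == 0 or m_norm == 0:
            out[i] = 0.0
        else:
            out[i] = float((s_c * m_c).sum() / (s_norm * m_norm))
    return out


def mcc_fitness(correlations) -> float:
    """Mean over sample standard deviation of the mode correlations."""
    r = np.asarray(correlations, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two correlations")
    std = float(r.std(ddof=1))
    if std == 0:
        return ZERO_STD_FITNESS_CAP
    return float(r.mean() / std)


def evaluate_params(
    signal: SlowTimeSignal,
    alpha: float,
    K: int,
    vmd_defaults: VMDParams = VMDParams(),
) -> tuple[float, FitnessReport, IMFSet]:
    """Fitness of one (alpha, K) candidate; VMD failures score -inf."""
    from dataclasses import replace

    params = replace(vmd_defaults, alpha=float(alpha), K=int(K))
    try:
        imfs = vmd_decompose(signal, params)
    except ValueError:
        report = FitnessReport(np.array([]), float("nan"),
                               float("-inf"), degenerate=True)
        return float("-inf"), report, None
    corr = imf_correlations(signal, imfs)
    fit = mcc_fitness(corr)
    report = FitnessReport(corr, float(corr.mean()), fit,
                           degenerate=(fit == ZERO_STD_FITNESS_CAP))
    return fit, report, imfs


def pso_optimize(
    signal: SlowTimeSignal,
    cfg: PSOConfig = PSOConfig(),
    vmd_defaults: VMDParams = VMDParams(),
) -> tuple[float, int, FitnessReport, list[float]]:
    """Global-best PSO over (alpha, K) maximizing the MCC fitness.

    Returns ``(alpha_best, K_best, report, trace)`` where ``trace`` is
    the per-iteration global best fitness (non-decreasing).  alpha is
    quantized to 0.1 at evaluation so that cached fitnesses are exactly
    reproducible from the stored decomposition.
    """
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([cfg.alpha_range[0], cfg.K_range[0]], dtype=float)
    hi = np.array([cfg.alpha_range[1], cfg.K_range[1]], dtype=float)
    span = hi - lo
    v_max = np.where(span > 0, 0.2 * span, 1.0)

    pos = lo + rng.uniform(size=(cfg.n_particles, 2)) * span
    vel = rng.uniform(-1, 1, size=(cfg.n_particles, 2)) * v_max

    cache: dict[tuple[float, int], tuple[float, FitnessReport]] = {}

    def fitness_at(p):
        alpha = round(float(np.clip(p[0], lo[0], hi[0])), 1)
        k = int(np.clip(round(p[1]), lo[1], hi[1]))
        key = (alpha, k)
        if key not in cache:
            fit, report, _ = evaluate_params(signal, alpha, k, vmd_defaults)
            cache[key] = (fit, report)
        return key, cache[key]

    pbest_pos = pos.copy()
    pbest_fit = np.full(cfg.n_particles, -np.inf)
    gbest_fit = -np.inf
    gbest_key = None
    gbest_report = None

    trace: list[float] = []
    w_start, w_end = cfg.inertia
    for it in range(cfg.n_iters):
        w = w_start + (w_end - w_start) * (
            it / max(cfg.n_iters - 1, 1))
        for i in range(cfg.n_particles):
            key, (fit, report) = fitness_at(pos[i])
            if fit > pbest_fit[i]:
                pbest_fit[i] = fit
                pbest_pos[i] = pos[i]
            if fit > gbest_fit:
                gbest_fit, gbest_key, gbest_report = fit, key, report
        trace.append(gbest_fit)
        r1 = rng.uniform(size=(cfg.n_particles, 2))
        r2 = rng.uniform(size=(cfg.n_particles, 2))
        vel = (w * vel
               + cfg.c1 * r1 * (pbest_pos - pos)
               + cfg.c2 * r2 * (gbest_key is not None) * (
                   np.array([gbest_key[0], gbest_key[1]]) - pos))
        vel = np.clip(vel, -v_max, v_max)
        pos = np.clip(pos + vel, lo, hi)

    return gbest_key[0], gbest_key[1], gbest_report, trace
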