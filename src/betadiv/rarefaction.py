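"""Sample-based species accumulation (rarefaction).

Two routes to the same curve:

* :func:`expected_richness` — the exact expectation of richness in a random
  t-subset of the T samples, from the per-taxon incidence counts:

      E[S_t] = sum_j [ 1 - C(T - T_j, t) / C(T, t) ]

  where T_j is the number of samples containing taxon j.  Binomial
  coefficients are evaluated in log space so the formula is stable out to
  hundreds of samples.

* :func:`accumulation_curve` — Monte-Carlo random accumulation: average the
  running richness over random orderings of the samples.  The analytic curve
  is attached to every result and serves as its own check.

Only interpolation is supported (1 <= t <= T); extrapolating past the number
of samples actually taken is refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = ["AccumulationCurve", "expected_richness", "accumulation_curve"]


def _as_binary(matrix) -> np.ndarray:
    x = np.asarray(matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else matrix)
    if x.ndim != 2:
        raise ValueError("incidence matrix must be 2-D (samples x taxa)")
    return (x > 0).astype(np.int64)


def _log_binom(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def expected_richness(matrix, t: int) -> float:
    """Exact expected richness in ``t`` of the matrix's samples.

    Parameters
    ----------
    matrix
        Binary samples x taxa array (rows are replicates/samples).
    t
        Number of samples drawn without replacement; must satisfy
        ``1 <= t <= T``.
    """
    x = _as_binary(matrix)
    T = x.shape[0]
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    if t > T:
        raise ValueError(
            f"extrapolation not supported: t={t} exceeds the {T} samples taken"
        )
    tj = x.sum(axis=0)
    tj = tj[tj > 0]  # taxa never observed contribute nothing
    if tj.size == 0:
        return 0.0
    # P(taxon j absent from the subset) = C(T - T_j, t) / C(T, t)
    rem = T - tj
    log_absent = np.where(
        rem >= t,
        _log_binom(rem.astype(float), float(t)) - _log_binom(np.float64(T), float(t)),
        -np.inf,
    )
    return float(np.sum(1.0 - np.exp(log_absent)))


@dataclass(frozen=True)
class AccumulationCurve:
    """Expected-richness curve for t = 1..T samples.

    ``expected`` is the exact analytic curve; ``mc_mean``/``mc_sd`` are the
    Monte-Carlo mean and SD over ``n_perm`` random sample orderings.
    """

    t: np.ndarray
    expected: np.ndarray
    mc_mean: np.ndarray | None
    mc_sd: np.ndarray | None
    n_perm: int
    seed: int | None

    def to_frame(self, unit: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t": self.t,
                "expected": self.expected,
                "mc_mean": self.mc_mean if self.mc_mean is not None else np.nan,
                "mc_sd": self.mc_sd if self.mc_sd is not None else np.nan,
            }
        )
        if unit is not None:
            df.insert(0, "unit", unit)
        return df


def accumulation_curve(
    matrix, n_perm: int = 1000, seed: int | None = None
) -> AccumulationCurve:
    """Random species-accumulation curve with its analytic counterpart.

    Richness under a random ordering of samples is accumulated as the running
    union; the Monte-Carlo mean over ``n_perm`` orderings estimates the same
    expectation :func:`expected_richness` computes exactly.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = _as_binary(matrix).astype(bool)
    T = x.shape[0]
    ts = np.arange(1, T + 1)
    analytic = np.array([expected_richness(x, int(t)) for t in ts])

    rng = np.random.default_rng(seed)
    richness = np.empty((n_perm, T), dtype=np.int64)
    for p in range(n_perm):
        order = rng.permutation(T)
        seen = np.logical_or.accumulate(x[order], axis=0)
        richness[p] = seen.sum(axis=1)
    return AccumulationCurve(
        t=ts,
        expected=analytic,
        mc_mean=richness.mean(axis=0),
        mc_sd=richness.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(T),
        n_perm=n_perm,
        seed=seed,
    )
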