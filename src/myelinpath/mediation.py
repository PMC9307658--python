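"""Serial two-mediator mediation with bootstrap inference.

The path system, fit by ordinary least squares, is

    M1 ~ a*X
    M2 ~ d21*M1 + (X)
    Y  ~ b2*M2 + b1*M1 + c'*X
    Y  ~ c_total*X            (total effect)

The headline estimand is the serial indirect effect ``a * d21 * b2``.
Inference resamples subjects with replacement, refits the path system per
resample, and reports the percentile (or BCa) confidence interval of the
serial indirect effect together with a bootstrap-sign two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator


@dataclass
class MediationResult:
    a: float
    d21: float
    b2: float
    b1: float
    c_prime: float
    c_total: float
    indirect_serial: float
    boot_ci_low: float | None
    boot_ci_high: float | None
    p_two_sided: float | None
    proportion_mediated: float
    n_boot: int
    seed: int | None
    n_degenerate_redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "d21": self.d21,
            "b2": self.b2,
            "b1": self.b1,
            "c_prime": self.c_prime,
            "c_total": self.c_total,
            "indirect_serial": self.indirect_serial,
            "boot_ci_low": self.boot_ci_low,
            "boot_ci_high": self.boot_ci_high,
            "p_two_sided": self.p_two_sided,
            "proportion_mediated": self.proportion_mediated,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_degenerate_redraws": self.n_degenerate_redraws,
        }


def _check_collinearity(arrs: dict[str, np.ndarray]) -> None:
    names = list(arrs)
    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            r = np.corrcoef(arrs[ni], arrs[nj])[0, 1]
            if abs(r) > 1 - 1e-10:
                raise np.linalg.LinAlgError(
                    f"singular fit: predictors {ni!r} and {nj!r} are collinear"
                )


def _ols(y: np.ndarray, *cols: np.ndarray) -> np.ndarray:
    """OLS slopes (intercept first) for a small design."""
    X = np.column_stack([np.ones(len(y)), *cols])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _fit_paths(x, m1, m2, y) -> dict[str, float]:
    a = _ols(m1, x)[1]
    b_m2 = _ols(m2, x, m1)
    beta_y = _ols(y, x, m1, m2)
    c_total = _ols(y, x)[1]
    return {
        "a": float(a),
        "d21": float(b_m2[2]),
        "x_to_m2": float(b_m2[1]),
        "b2": float(beta_y[3]),
        "b1": float(beta_y[2]),
        "c_prime": float(beta_y[1]),
        "c_total": float(c_total),
    }


def _batched_paths(x, m1, m2, y, idx: np.ndarray) -> np.ndarray:
    """Serial indirect effect for every bootstrap resample (rows of ``idx``).

    Solves the three per-resample regressions through batched normal
    equations; returns the (B,) vector of ``a * d21 * b2``.
    """
    B, n = idx.shape
    ones = np.ones((B, n))

    def solve(cols: list[np.ndarray], resp: np.ndarray) -> np.ndarray:
        X = np.stack([ones] + cols, axis=2)          # (B, n, p)
        xtx = np.einsum("bnp,bnq->bpq", X, X)
        xty = np.einsum("bnp,bn->bp", X, resp)
        return np.linalg.solve(xtx, xty[..., None])[..., 0]  # (B, p)

    xs, m1s, m2s, ys = x[idx], m1[idx], m2[idx], y[idx]
    a = solve([xs], m1s)[:, 1]
    d21 = solve([xs, m1s], m2s)[:, 2]
    b2 = solve([xs, m1s, m2s], ys)[:, 3]
    return a * d21 * b2


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


class SerialMediation(BaseEstimator):
    """Serial two-mediator mediation model X -> M1 -> M2 -> Y.

    Parameters
    ----------
    standardize : bool
        Z-score all four variables before fitting (standardized-scale paths).
    n_boot : int
        Bootstrap repetitions; 0 skips bootstrap inference.
    ci : float
        Confidence level of the bootstrap interval.
    ci_method : {'percentile', 'bca'}
        Interval construction for the serial indirect effect.
    random_state : int or None
        Seed of the resampling sequence.

    ``fit(X, y)`` takes ``X`` of shape (n, 3) with columns (predictor,
    mediator 1, mediator 2) and the outcome ``y``; fitted paths land in
    ``a_``, ``d21_``, ``b2_``, ``b1_``, ``c_prime_``, ``c_total_``,
    ``indirect_`` with bootstrap results in ``boot_ci_``, ``p_value_``.
    """

    def __init__(
        self,
        standardize: bool = True,
        n_boot: int = 10000,
        ci: float = 0.95,
        ci_method: str = "percentile",
        random_state: int | None = None,
    ):
        self.standardize = standardize
        self.n_boot = n_boot
        self.ci = ci
        self.ci_method = ci_method
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n, 3): predictor, mediator 1, mediator 2")
        n = len(y)
        if X.shape[0] != n:
            raise ValueError("X and y lengths differ")
        if n < 10:
            raise ValueError(f"mediation requires n >= 10, got {n}")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("missing values are not supported")
        x, m1, m2 = X[:, 0], X[:, 1], X[:, 2]
        if self.standardize:
            x, m1, m2, yy = map(_standardize, (x, m1, m2, y))
        else:
            yy = y
        _check_collinearity({"x": x, "m1": m1, "m2": m2, "y": yy})

        paths = _fit_paths(x, m1, m2, yy)
        for name, value in paths.items():
            setattr(self, f"{name}_", value)
        self.indirect_ = paths["a"] * paths["d21"] * paths["b2"]
        self.proportion_mediated_ = (
            self.indirect_ / self.c_total_ if self.c_total_ != 0 else float("nan")
        )

        self.boot_ci_ = (None, None)
        self.p_value_ = None
        self.boot_estimates_ = None
        self.n_degenerate_redraws_ = 0
        if self.n_boot:
            self._bootstrap(x, m1, m2, yy)
        return self

    def _bootstrap(self, x, m1, m2, y):
        n = len(y)
        rng = np.random.default_rng(self.random_state)
        idx = rng.integers(0, n, size=(self.n_boot, n))
        # redraw resamples in which any variable is constant
        redraws = 0
        for _ in range(100):
            degenerate = np.zeros(len(idx), dtype=bool)
            for v in (x, m1, m2, y):
                vals = v[idx]
                degenerate |= np.all(vals == vals[:, :1], axis=1)
            if not degenerate.any():
                break
            redraws += int(degenerate.sum())
            idx[degenerate] = rng.integers(0, n, size=(int(degenerate.sum()), n))
        boot = _batched_paths(x, m1, m2, y, idx)
        alpha = 1.0 - self.ci
        if self.ci_method == "bca":
            lo, hi = self._bca_interval(boot, x, m1, m2, y, alpha)
        else:
            lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
        share_le = np.mean(boot <= 0)
        share_ge = np.mean(boot >= 0)
        p = max(2.0 * min(share_le, share_ge), 1.0 / self.n_boot)
        self.boot_ci_ = (float(lo), float(hi))
        self.p_value_ = float(min(p, 1.0))
        self.boot_estimates_ = boot
        self.n_degenerate_redraws_ = redraws

    def _bca_interval(self, boot, x, m1, m2, y, alpha):
        n = len(y)
        z0 = stats.norm.ppf(np.clip(np.mean(boot < self.indirect_), 1e-9, 1 - 1e-9))
        # jackknife acceleration
        jack = np.empty(n)
        full = np.arange(n)
        for i in range(n):
            keep = np.delete(full, i)
            p = _fit_paths(x[keep], m1[keep], m2[keep], y[keep])
            jack[i] = p["a"] * p["d21"] * p["b2"]
        diff = jack.mean() - jack
        denom = 6.0 * (diff**2).sum() ** 1.5
        acc = (diff**3).sum() / denom if denom > 0 else 0.0
        z = stats.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
        adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - acc * (z0 + z)))
        return np.quantile(boot, adj)

    def result(self) -> MediationResult:
        return MediationResult(
            a=self.a_,
            d21=self.d21_,
            b2=self.b2_,
            b1=self.b1_,
            c_prime=self.c_prime_,
            c_total=self.c_total_,
            indirect_serial=self.indirect_,
            boot_ci_low=self.boot_ci_[0],
            boot_ci_high=self.boot_ci_[1],
            p_two_sided=self.p_value_,
            proportion_mediated=self.proportion_mediated_,
            n_boot=self.n_boot,
            seed=self.random_state,
            n_degenerate_redraws=self.n_degenerate_redraws_,
        )


def fit_serial_mediation(x, m1, m2, y, standardize: bool = True) -> MediationResult:
    """Point estimates of the serial path system (no bootstrap)."""
    est = SerialMediation(standardize=standardize, n_boot=0)
    return est.fit(np.column_stack([x, m1, m2]), np.asarray(y, dtype=float)).result()


def bootstrap_indirect(
    x,
    m1,
    m2,
    y,
    n_boot: int = 10000,
    seed: int | None = None,
    standardize: bool = True,
    ci_method: str = "percentile",
) -> MediationResult:
    """Full serial mediation with bootstrap CI and sign-based p-value."""
    est = SerialMediation(
        standardize=standardize,
        n_boot=n_boot,
        ci_method=ci_method,
        random_state=seed,
    )
    return est.fit(np.column_stack([x, m1, m2]), np.asarray(y, dtype=float)).result()


def path_diagram(result: MediationResult) -> str:
    """Plain-text path diagram of a fitted serial mediation."""
    return (
        f"        a={result.a:+.3f}        d21={result.d21:+.3f}       b2={result.b2:+.3f}\n"
        f"  X ----------> M1 ----------> M2 ----------> Y\n"
        f"  |                                           ^\n"
        f"  +----------------- c'={result.c_prime:+.3f} ------------+\n"
        f"  serial indirect a*d21*b2 = {result.indirect_serial:+.4f}"
        + (
            f"  [95% CI {result.boot_ci_low:+.4f}, {result.boot_ci_high:+.4f}]"
            if result.boot_ci_low is not None
            else ""
        )
        + f"\n  total effect c = {result.c_total:+.4f}"
        f"  (proportion mediated {result.proportion_mediated:.3f})"
    )
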