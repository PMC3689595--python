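"""Statistical procedures used throughout the pipeline.

Yates-corrected chi-square, Spearman rank correlation (exact permutation p
for small n), Mantel and multi-predictor Mantel row-permutation tests, a
logistic (binary logit) fit by IRLS with Wald tests, the likelihood-ratio
test, and average-linkage city-block hierarchical clustering.

Permutation p-values use the add-one convention: p = (1 + #extreme) /
(n_perm + 1), so they are never exactly zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage

from .errors import ValidationError


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Labelled 2x2 table of non-negative counts."""

    counts: tuple[tuple[float, float], tuple[float, float]]
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.shape != (2, 2):
            raise ValidationError("contingency table must be 2x2")
        if (arr < 0).any():
            raise ValidationError("negative count in contingency table")
        if arr.sum() <= 0:
            raise ValidationError("contingency table is empty")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.array, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    n_permutations: int | None = None
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class LogitFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int
    separation: bool = False
    names: tuple[str, ...] = ()


def yates_chi_square(table: ContingencyTable2x2) -> TestResult:
    """Continuity-corrected chi-square test of association on a 2x2 table.

    statistic = sum over cells of max(|O - E| - 0.5, 0)^2 / E, df = 1.
    Raises if any row or column marginal is zero.
    """
    obs = table.array
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValidationError("zero marginal: expected counts undefined")
    expected = np.outer(row, col) / obs.sum()
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    stat = float((adj ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(statistic=stat, p_value=p, df=1, method="yates_chi_square")


def spearman(x, y, exact_threshold: int = 10) -> TestResult:
    """Spearman rank correlation with mid-ranks for ties.

    p-value is computed by exact permutation enumeration for n <= 10 and by
    the t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValidationError("constant vector: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_threshold:
        p = _spearman_exact_p(rx, ry, rho)
        method = "spearman_exact"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        method = "spearman_t"
    return TestResult(statistic=rho, p_value=p, method=method, extra={"n": n})


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    target = abs(float(rxc @ ryc))  # |covariance numerator| is monotone in |rho|
    count = 0
    total = 0
    batch: list[tuple[int, ...]] = []

    def flush(batch: list[tuple[int, ...]]) -> int:
        perm = np.array(batch, dtype=np.intp)
        vals = np.abs(ryc[perm] @ rxc)
        return int((vals >= target - 1e-12).sum())

    for p in itertools.permutations(range(n)):
        batch.append(p)
        total += 1
        if len(batch) == 100_000:
            count += flush(batch)
            batch = []
    if batch:
        count += flush(batch)
    return count / total


def _flatten(m) -> np.ndarray:
    arr = np.asarray(m, dtype=float)
    return arr.reshape(-1)


def mantel(dep, indep, n_perm: int = 999, seed: int | None = None) -> TestResult:
    """Row-permutation test of correlation between two equal-shape matrices.

    The statistic is the Pearson correlation of the flattened matrices; the
    null distribution is built by permuting the rows of ``dep``.  Two-sided,
    add-one p.
    """
    d = np.asarray(dep, dtype=float)
    i = np.asarray(indep, dtype=float)
    if d.shape != i.shape:
        raise ValidationError("matrices must share a shape")
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    dv, iv = d.reshape(-1), i.reshape(-1)
    if dv.std() == 0 or iv.std() == 0:
        raise ValidationError("zero-variance matrix: correlation undefined")
    r_obs = float(np.corrcoef(dv, iv)[0, 1])
    rng = np.random.default_rng(seed)
    n_rows = d.shape[0]
    hits = 0
    ic = iv - iv.mean()
    ic_norm = math.sqrt(float(ic @ ic))
    for _ in range(n_perm):
        perm = rng.permutation(n_rows)
        pv = d[perm].reshape(-1)
        pc = pv - pv.mean()
        r = float(pc @ ic) / (math.sqrt(float(pc @ pc)) * ic_norm)
        if abs(r) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return TestResult(statistic=r_obs, p_value=p, method="mantel",
                      n_permutations=n_perm)


def multi_mantel(dep, indeps, n_perm: int = 999, seed: int | None = None) -> dict:
    """Multiple regression of a flattened matrix on flattened predictors.

    Coefficients by OLS; per-predictor two-sided permutation p-values by
    permuting the rows of ``dep`` and refitting.
    """
    d = np.asarray(dep, dtype=float)
    mats = [np.asarray(m, dtype=float) for m in indeps]
    for m in mats:
        if m.shape != d.shape:
            raise ValidationError("all matrices must share a shape")
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    y = d.reshape(-1)
    X = np.column_stack([np.ones(y.size)] + [m.reshape(-1) for m in mats])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rng = np.random.default_rng(seed)
    n_rows = d.shape[0]
    hits = np.zeros(len(mats), dtype=int)
    pinv = np.linalg.pinv(X)
    for _ in range(n_perm):
        yp = d[rng.permutation(n_rows)].reshape(-1)
        bp = pinv @ yp
        hits += (np.abs(bp[1:]) >= np.abs(beta[1:]) - 1e-12).astype(int)
    p = (1 + hits) / (n_perm + 1)
    return {
        "intercept": float(beta[0]),
        "coefficients": beta[1:].copy(),
        "p_values": p,
        "n_permutations": n_perm,
        "method": "multi_mantel",
    }


def logit_irls(
    X: np.ndarray,
    y: np.ndarray,
    names: tuple[str, ...] = (),
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogitFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``X`` must already include an intercept column.  Perfect separation is
    flagged (``separation=True``, ``converged=False``) rather than silently
    returning diverged estimates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be (n, p) and y (n,)")
    if X.shape[0] < 6:
        raise ValidationError("need at least 6 observations")
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise ValidationError("y must be binary 0/1")
    if len(classes) < 2:
        raise ValidationError("both outcome classes must be present")

    n, p = X.shape
    beta = np.zeros(p)
    ll_prev = -np.inf
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(y @ np.log(mu + 1e-300) + (1 - y) @ np.log(1 - mu + 1e-300))
        w = mu * (1.0 - mu)
        if np.max(np.abs(beta)) > 1e4 or np.max(w) < 1e-8:
            separation = True
            break
        XtW = X.T * w
        try:
            delta = np.linalg.solve(XtW @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            separation = True
            break
        beta = beta + delta
        if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll

    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(y @ np.log(mu + 1e-300) + (1 - y) @ np.log(1 - mu + 1e-300))
    w = mu * (1.0 - mu)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    return LogitFit(
        coefficients=beta, standard_errors=se, wald_z=z, wald_p=pvals,
        log_likelihood=ll, converged=converged and not separation,
        n_iterations=it, separation=separation,
        names=names or tuple(f"x{j}" for j in range(p)),
    )


def logit_fit(table: pd.DataFrame) -> LogitFit:
    """Binary logit of overlap status on the four dS/dN predictors."""
    from .annotation_io import validate_dnds_table

    df = validate_dnds_table(table)
    predictors = ["gene1_dS", "gene1_dN", "gene2_dS", "gene2_dN"]
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in predictors]
    )
    y = df["overlap_status"].to_numpy(dtype=float)
    return logit_irls(X, y, names=("intercept", *predictors))


def likelihood_ratio_test(ll_null: float, ll_alt: float, df: int) -> TestResult:
    """2*(ll_alt - ll_null) against chi-square(df); negative stats clip to 0."""
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(sps.chi2.sf(stat, df=df))
    return TestResult(statistic=stat, p_value=p, df=df, method="lrt")


def hcluster_cityblock(matrix) -> np.ndarray:
    """Average-linkage agglomerative clustering with city-block distance.

    Returns a scipy linkage matrix (merge list with heights).
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 rows")
    return linkage(arr, method="average", metric="cityblock")


def results_to_frame(results: dict[str, TestResult]) -> pd.DataFrame:
    rows = [
        dict(
            name=k, method=r.method, statistic=r.statistic,
            df="" if r.df is None else r.df, p_value=r.p_value,
            n_permutations="" if r.n_permutations is None else r.n_permutations,
        )
        for k, r in results.items()
    ]
    return pd.DataFrame(rows)
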