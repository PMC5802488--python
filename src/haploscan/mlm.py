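"""Mixed linear model: REML variance components and haplotype association.

The scan model is

    y = X b + Z1 u + Z2 v + e,   u ~ N(0, G s2_u),  v ~ N(0, G_t s2_v),
                                 e ~ N(0, I s2_e)

with y the binary 0/1 observations analysed on the observed scale, X the
fixed effects (intercept, haplotype dosage when testing, sex, age, age²,
optional batch/centre), G a genomic relationship matrix and G_t its
thresholded companion modelling only closer relatives (one record per
individual, so Z1 = Z2 = I).  The replication-style model drops the v
term.

Variance components are estimated once under the null (no haplotype) by
average-information REML with an EM-REML fallback, then held fixed while
each haplotype dosage is tested by a generalized-least-squares Wald test
(the MLMA convention): with P the REML projection matrix at the null
V = s2_u G + s2_v G_t + s2_e I,

    beta = d' P y / d' P d,    se = (d' P d)^{-1/2}.

Effects on the observed 0/1 scale are converted to odds ratios through
the log-odds approximation beta / (cf (1 - cf)) with cf the case
fraction; an exact logistic refit (ignoring relatedness) is available as
a cross-check.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import linalg, stats

from .genmap import Window

Z_95 = 1.959964  # two-sided 95% normal quantile


class RemlError(RuntimeError):
    pass


@dataclasses.dataclass
class VarComp:
    """Converged REML variance components (residual last)."""

    names: tuple[str, ...]
    sigma2: tuple[float, ...]
    loglik_restricted: float
    n_iter: int
    converged: bool
    unidentifiable: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.sigma2))

    @property
    def genetic_variance(self) -> float:
        return float(sum(s for nm, s in zip(self.names, self.sigma2) if nm != "e"))

    @property
    def total_variance(self) -> float:
        return float(sum(self.sigma2))


@dataclasses.dataclass
class AssociationResult:
    """Wald test of one haplotype allele's dosage in the mixed model."""

    window: Window | None
    allele_string: str
    freq: float
    beta: float
    se: float
    z: float
    p: float
    or_: float
    or_lo: float
    or_hi: float
    var_explained_raw: float
    skipped: bool = False
    reason: str = ""


def build_design(
    phen,
    covariates: tuple[str, ...] = ("sex", "age"),
    add_age_squared: bool = True,
) -> np.ndarray:
    """Fixed-effect design: intercept, covariates, age², dummy-coded factors.

    Aliased (rank-deficient) columns are dropped deterministically,
    last-in first.
    """
    cols = [np.ones(len(phen))]
    names = ["intercept"]
    for c in covariates:
        v = phen[c]
        if v.dtype == object or str(v.dtype).startswith("category"):
            levels = sorted(map(str, set(v)))
            for lev in levels[1:]:  # first level is the reference
                cols.append((v.astype(str) == lev).astype(float).values)
                names.append(f"{c}[{lev}]")
        else:
            cols.append(np.asarray(v, dtype=float))
            names.append(c)
            if c == "age" and add_age_squared:
                a = np.asarray(v, dtype=float)
                cols.append(a * a)
                names.append("age_sq")
    X = np.column_stack(cols)
    # drop aliased columns, keeping earlier columns
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    return X[:, keep]


def _chol_v(V: np.ndarray):
    # thresholded GRMs need not be PSD, so escalate the ridge until V
    # factorizes; beyond 1e-3 of the mean diagonal we call it non-PD
    scale = float(np.mean(np.diag(V)))
    for jitter in (0.0, 1e-8, 1e-6, 1e-4, 1e-3):
        try:
            return linalg.cho_factor(
                V + jitter * scale * np.eye(V.shape[0]), lower=True
            )
        except linalg.LinAlgError:
            continue
    raise RemlError("covariance matrix not positive definite")


def _reml_pieces(y, X, kernels, sigma2):
    """P, Py, restricted log-likelihood for the current variance components."""
    n = len(y)
    V = np.zeros((n, n))
    for s, K in zip(sigma2, kernels):
        V += s * K
    cho = _chol_v(V)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    Vinv = linalg.cho_solve(cho, np.eye(n))
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    sign, logdet_x = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise RemlError("X'V⁻¹X singular; design rank-deficient")
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    Py = P @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return P, Py, ll


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
    names: tuple[str, ...] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> VarComp:
    """AI-REML over (s2 per kernel, s2_e), EM fallback, components floored ≥ 0.

    ``kernels`` are the genetic covariance kernels (G, and optionally G_t);
    the residual identity kernel is appended internally.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if n < 2 or np.ptp(y) == 0:
        raise RemlError("degenerate phenotype: y is constant")
    if names is None:
        names = tuple(f"k{i}" for i in range(len(kernels)))
    all_k = [np.asarray(K, dtype=float) for K in kernels] + [np.eye(n)]
    all_names = (*names, "e")
    vary = float(np.var(y, ddof=1))
    floor = 1e-6 * vary
    # residual-heavy start: thresholded GRMs can be indefinite, so a large
    # genetic share can make the initial V non-PD; shrink until it factorizes
    m_gen = len(kernels)
    gen_share = 0.2
    for _ in range(8):
        sigma2 = np.full(len(all_k), gen_share * vary / max(m_gen, 1))
        sigma2[-1] = (1.0 - gen_share) * vary
        try:
            P, Py, ll = _reml_pieces(y, X, all_k, sigma2)
            break
        except RemlError:
            gen_share *= 0.3
    else:
        raise RemlError("no positive-definite starting covariance found")
    n_iter = 0
    converged = False
    ai = np.eye(len(all_k))
    m = len(all_k)
    for n_iter in range(1, max_iter + 1):
        KPy = [K @ Py for K in all_k]
        trPK = np.array([float(np.sum(P * K)) for K in all_k])
        yPKPy = np.array([float(Py @ KPy_i) for KPy_i in KPy])
        grad = -0.5 * (trPK - yPKPy)
        PKPy = [P @ v for v in KPy]
        ai = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                ai[i, j] = ai[j, i] = 0.5 * float(KPy[i] @ PKPy[j])
        # active set: components pinned at the floor with an inward-pointing
        # gradient stay fixed there; AI/EM updates act on the rest
        active = ~((sigma2 <= floor * (1 + 1e-9)) & (grad < 0))
        if not active.any():
            converged = True
            break
        # AI step over the active set with step-halving; EM fallback
        try:
            delta = np.linalg.solve(ai[np.ix_(active, active)], grad[active])
        except np.linalg.LinAlgError:
            delta = None
        stepped = False
        if delta is not None:
            scale = 1.0
            for _ in range(12):
                cand = sigma2.copy()
                cand[active] = np.maximum(cand[active] + scale * delta, floor)
                try:
                    P_new, Py_new, ll_new = _reml_pieces(y, X, all_k, cand)
                except RemlError:
                    scale *= 0.5
                    continue
                if ll_new >= ll - 1e-12:
                    sigma2, P, Py = cand, P_new, Py_new
                    dll = ll_new - ll
                    ll = ll_new
                    stepped = True
                    break
                scale *= 0.5
        if not stepped:
            em_step = sigma2[active] ** 2 * (yPKPy[active] - trPK[active]) / n
            for _ in range(8):
                cand = sigma2.copy()
                cand[active] = np.maximum(sigma2[active] + em_step, floor)
                try:
                    P, Py, ll_new = _reml_pieces(y, X, all_k, cand)
                    break
                except RemlError:
                    em_step *= 0.5
            else:
                raise RemlError("EM step cannot keep V positive definite")
            dll = ll_new - ll
            ll = ll_new
            sigma2 = cand
        if abs(dll) < tol:
            converged = True
            break
    unident = bool(np.linalg.cond(ai) > 1e8)
    if unident:
        warnings.warn(
            "variance components near-unidentifiable (aliased kernels)",
            stacklevel=2,
        )
    return VarComp(
        names=all_names,
        sigma2=tuple(float(s) for s in sigma2),
        loglik_restricted=float(ll),
        n_iter=n_iter,
        converged=converged,
        unidentifiable=unident,
    )


def beta_to_or(
    beta: float, se: float, case_fraction: float
) -> tuple[float, float, float]:
    """Observed-scale effect → odds ratio with 95% CI.

    Uses the log-odds approximation log(OR) ≈ beta / (cf (1 − cf)), valid
    for modest effects on a binary trait analysed by a linear model.
    """
    if not 0.0 < case_fraction < 1.0:
        raise ValueError("case_fraction must be in (0, 1)")
    k = case_fraction * (1.0 - case_fraction)
    log_or = beta / k
    se_log = se / k
    return (
        float(np.exp(log_or)),
        float(np.exp(log_or - Z_95 * se_log)),
        float(np.exp(log_or + Z_95 * se_log)),
    )


def variance_explained(p: float, beta: float, denom: float | None = None) -> float:
    """Population-level variance contributed by an allele: 2 p (1−p) beta².

    With ``denom`` given (phenotypic or total genetic variance), the
    contribution is returned as a fraction of that denominator.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    raw = 2.0 * p * (1.0 - p) * beta * beta
    return raw / denom if denom is not None else raw


class MlmScan:
    """Per-haplotype Wald tests with the null-model V held fixed.

    The projection P (and Py) under the null variance components is
    factorized once; each haplotype dosage d is then tested in O(n²).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        varcomp: VarComp,
        kernels: list[np.ndarray],
    ) -> None:
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        sig = varcomp.sigma2
        if len(sig) != len(kernels) + 1:
            raise ValueError("varcomp does not match the kernel list")
        all_k = [np.asarray(K, dtype=float) for K in kernels] + [np.eye(len(y))]
        self.P, self.Py, _ = _reml_pieces(y, X, all_k, np.asarray(sig))
        self.y = y
        self.X = X
        self.case_fraction = float(np.mean(y))
        self.varcomp = varcomp
        # orthonormal basis of X for alias detection
        self._Q, _ = np.linalg.qr(X)

    def _check_aliased(self, d: np.ndarray) -> None:
        resid = d - self._Q @ (self._Q.T @ d)
        if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(d), 1.0):
            raise ValueError("aliased covariate: dosage in span of fixed effects")

    def test(
        self,
        dosage: np.ndarray,
        window: Window | None = None,
        allele_string: str = "",
        freq: float | None = None,
    ) -> AssociationResult:
        d = np.asarray(dosage, dtype=float)
        if np.ptp(d) == 0:
            return AssociationResult(
                window=window,
                allele_string=allele_string,
                freq=float(freq) if freq is not None else float("nan"),
                beta=float("nan"),
                se=float("nan"),
                z=float("nan"),
                p=float("nan"),
                or_=float("nan"),
                or_lo=float("nan"),
                or_hi=float("nan"),
                var_explained_raw=float("nan"),
                skipped=True,
                reason="monomorphic in analyzed set",
            )
        self._check_aliased(d)
        den = float(d @ (self.P @ d))
        if den <= 0:
            raise ValueError("non-positive quadratic form; V not PD?")
        beta = float(d @ self.Py) / den
        se = den**-0.5
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        f = float(freq) if freq is not None else float(np.mean(d) / 2.0)
        or_, lo, hi = beta_to_or(beta, se, self.case_fraction)
        ve = variance_explained(f, beta) if 0.0 < f < 1.0 else 0.0
        return AssociationResult(
            window=window,
            allele_string=allele_string,
            freq=f,
            beta=beta,
            se=se,
            z=z,
            p=max(p, 5e-324),
            or_=or_,
            or_lo=lo,
            or_hi=hi,
            var_explained_raw=ve,
        )

    def test_many(self, dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised (beta, se, p) for an (m, n) dosage matrix.

        Constant rows yield NaN; alias checking is the caller's concern.
        """
        D = np.asarray(dosages, dtype=float)
        ok = np.ptp(D, axis=1) > 0
        beta = np.full(D.shape[0], np.nan)
        se = np.full(D.shape[0], np.nan)
        if ok.any():
            Dv = D[ok]
            PD = self.P @ Dv.T
            den = np.einsum("ij,ji->i", Dv, PD)
            beta[ok] = (Dv @ self.Py) / den
            se[ok] = den**-0.5
        p = 2.0 * stats.norm.sf(np.abs(beta / se))
        return beta, se, p


def logistic_or_crosscheck(
    y: np.ndarray, X: np.ndarray, dosage: np.ndarray
) -> tuple[float, float, float]:
    """Plain logistic-regression OR for the dosage (relatedness ignored).

    A cross-check on the observed-scale OR conversion, not a replacement
    for the mixed-model test.
    """
    import statsmodels.api as sm

    Xd = np.column_stack([X, dosage])
    fit = sm.Logit(y, Xd).fit(disp=0)
    b = fit.params[-1]
    s = fit.bse[-1]
    return float(np.exp(b)), float(np.exp(b - Z_95 * s)), float(np.exp(b + Z_95 * s))
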