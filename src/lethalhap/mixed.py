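"""Pedigree mixed-model machinery.

Implements the numerator-relationship-matrix inverse (Henderson/Quaas rules
with inbreeding, optional unknown-parent groups), average-information REML
with an EM fallback, BLUP via Henderson's mixed-model equations, corrected
phenotypes (breeding value + permanent environment + residual), and the
heritability formulas used for the stillbirth and fertility traits.

Internally a model is a response vector ``y``, a dense fixed-effects design
``X`` and a list of :class:`RandomTerm` objects; :func:`build_design`
constructs these from a records table and a :class:`ModelSpec`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

logger = logging.getLogger("lethalhap")


class MixedModelError(Exception):
    pass


# ---------------------------------------------------------------------------
# pedigree relationship machinery
# ---------------------------------------------------------------------------

def kinship_matrix(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    ``sire``/``dam`` are row indices into the (topologically sorted) pedigree,
    -1 for unknown.  Quadratic in pedigree size; intended for moderate
    pedigrees and as the reference for :func:`a_inverse`.
    """
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    return A


def inbreeding_coefficients(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients F for a sorted pedigree.

    Memoised recursive relationship evaluation; fast on the shallow AI
    pedigrees this package targets.
    """
    n = len(sire)
    memo: dict[tuple[int, int], float] = {}

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * n + 1000))
    try:
        def rel(i: int, j: int) -> float:
            if i < 0 or j < 0:
                return 0.0
            if i < j:
                i, j = j, i
            key = (i, j)
            val = memo.get(key)
            if val is not None:
                return val
            if i == j:
                val = 1.0 + 0.5 * rel(sire[i], dam[i])
            else:
                # i is the later-born; its parents precede it
                val = 0.5 * (rel(sire[i], j) + rel(dam[i], j))
            memo[key] = val
            return val

        F = np.zeros(n)
        for i in range(n):
            if sire[i] >= 0 and dam[i] >= 0:
                F[i] = 0.5 * rel(sire[i], dam[i])
    finally:
        sys.setrecursionlimit(old_limit)
    return F


def a_inverse(
    pedigree,
    use_upg: bool = False,
) -> tuple[sparse.csr_matrix, list]:
    """Sparse inverse of the numerator relationship matrix.

    Henderson's rules with inbreeding accounted for.  With ``use_upg``,
    unknown parents map to unknown-parent-group columns (Westell–Quaas); the
    returned matrix is then of order ``n + n_groups`` with group labels
    returned second.  Without groups the group list is empty.
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    F = inbreeding_coefficients(sire, dam)

    groups: list = []
    gidx: dict = {}
    sire_col = sire.copy()
    dam_col = dam.copy()
    if use_upg:
        upg = pedigree.table["upg"].to_numpy()
        for i in range(n):
            label = upg[i] if upg[i] not in ("", None) else "UPG-default"
            for arr in (sire_col, dam_col):
                if arr[i] < 0:
                    if label not in gidx:
                        gidx[label] = n + len(groups)
                        groups.append(label)
                    arr[i] = gidx[label]

    size = n + len(groups)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        Fs = F[sire[i]] if sire[i] >= 0 else 0.0
        Fd = F[dam[i]] if dam[i] >= 0 else 0.0
        n_known = int(sire[i] >= 0) + int(dam[i] >= 0)
        if n_known == 2:
            d = 0.5 - 0.25 * (Fs + Fd)
        elif n_known == 1:
            d = 0.75 - 0.25 * (Fs if sire[i] >= 0 else Fd)
        else:
            d = 1.0
        alpha = 1.0 / d
        parents = [p for p in (sire_col[i], dam_col[i]) if p >= 0]
        add(i, i, alpha)
        for p in parents:
            add(i, p, -0.5 * alpha)
            add(p, i, -0.5 * alpha)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * alpha)

    Ainv = sparse.csr_matrix((vals, (rows, cols)), shape=(size, size))
    if groups:
        # tiny ridge keeps the group block non-singular when groups are fit
        # as random effects in the MME
        ridge = sparse.csr_matrix(
            (np.full(len(groups), 1e-8), (range(n, size), range(n, size))),
            shape=(size, size),
        )
        Ainv = Ainv + ridge
    return Ainv, groups


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class RandomTerm:
    """One random effect: ``u ~ N(0, K sigma2)`` with incidence ``Z``.

    ``kinv`` is the sparse inverse of K (None means identity); ``logdet_k``
    is log|K| (0 for identity)."""

    name: str
    Z: sparse.csr_matrix
    kinv: sparse.spmatrix | None = None
    logdet_k: float = 0.0
    levels: list = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]


@dataclass
class ModelSpec:
    """Declarative model: response column, fixed terms, random terms.

    ``fixed_terms``: list of column names treated as categorical factors, or
    ``("cov", name)`` tuples for numeric covariates.
    ``random_terms``: list of ``(name, column, kind)`` with kind in
    {"pedigree-additive", "pedigree-maternal", "identity-PE", "identity-HY",
    "identity-IYM", "identity"}.  Pedigree kinds share one A-inverse over the
    supplied pedigree; a maternal+direct pair with a genetic covariance is
    handled by :func:`solve_blup` via ``genetic_cov``.
    """

    response: str
    fixed_terms: list = field(default_factory=list)
    random_terms: list = field(default_factory=list)
    genetic_cov: bool = False


@dataclass
class VarianceComponents:
    """Variance components keyed by term name plus ``residual``; the optional
    direct-maternal covariance lives in ``cov_direct_maternal``."""

    values: dict
    cov_direct_maternal: float = 0.0

    def __getitem__(self, key):
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)


@dataclass
class MixedModelFit:
    varcomp: VarianceComponents
    fixed_labels: list
    fixed_solutions: np.ndarray
    random_solutions: dict  # term name -> (levels, values)
    residuals: np.ndarray
    fitted: np.ndarray
    y: np.ndarray
    dropped_fixed: list = field(default_factory=list)
    _cov_solver: object = field(default=None, repr=False)
    n_fixed: int = 0

    def fixed_effect(self, label: str) -> float:
        return float(self.fixed_solutions[self.fixed_labels.index(label)])

    def fixed_se(self, labels) -> np.ndarray:
        """Standard errors of chosen fixed effects from the inverse of the
        MME coefficient matrix (selected-column solves)."""
        idx = [self.fixed_labels.index(lab) for lab in labels]
        out = np.empty(len(idx))
        for k, j in enumerate(idx):
            e = np.zeros(self._cov_dim)
            e[j] = 1.0
            col = self._cov_solver.solve(e)
            out[k] = np.sqrt(max(col[j], 0.0))
        return out

    def fixed_cov(self, labels) -> np.ndarray:
        idx = [self.fixed_labels.index(lab) for lab in labels]
        cols = np.zeros((self._cov_dim, len(idx)))
        for k, j in enumerate(idx):
            e = np.zeros(self._cov_dim)
            e[j] = 1.0
            cols[:, k] = self._cov_solver.solve(e)
        return cols[idx, :]

    @property
    def _cov_dim(self) -> int:
        return self.n_fixed + sum(
            len(v[0]) for v in self.random_solutions.values()
        )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def dummy_encode(values: pd.Series, prefix: str) -> tuple[sparse.csr_matrix, list]:
    """Full-rank treatment coding: reference level is the first observed."""
    cats = list(dict.fromkeys(values))
    cols = []
    labels = []
    codes = pd.Categorical(values, categories=cats).codes
    n = len(values)
    for k, cat in enumerate(cats[1:], start=1):
        col = np.zeros(n)
        col[codes == k] = 1.0
        cols.append(col)
        labels.append(f"{prefix}[{cat}]")
    if cols:
        X = np.column_stack(cols)
    else:
        X = np.empty((n, 0))
    return X, labels


def incidence(values, levels: list) -> sparse.csr_matrix:
    lut = {lev: i for i, lev in enumerate(levels)}
    rows = np.arange(len(values))
    cols = np.array([lut[v] for v in values])
    return sparse.csr_matrix(
        (np.ones(len(values)), (rows, cols)), shape=(len(values), len(levels))
    )


def build_design(
    data: pd.DataFrame,
    spec: ModelSpec,
    pedigree=None,
    use_upg: bool = False,
):
    """Build (y, X, fixed_labels, random_terms) from a records table.

    Pedigree-kind random terms index the full pedigree (every animal gets a
    level); identity kinds index the observed levels of their column.
    """
    y = data[spec.response].to_numpy(dtype=float)
    n = len(data)
    X_parts = [np.ones((n, 1))]
    labels = ["intercept"]
    for term in spec.fixed_terms:
        if isinstance(term, tuple) and term[0] == "cov":
            X_parts.append(data[term[1]].to_numpy(dtype=float).reshape(-1, 1))
            labels.append(term[1])
        else:
            Xc, lab = dummy_encode(data[term].astype(str), term)
            X_parts.append(Xc)
            labels.extend(lab)
    X = np.column_stack(X_parts)
    X, labels, dropped = _drop_aliased(X, labels)
    if dropped:
        logger.info("dropped aliased fixed-effect columns: %s", dropped)

    terms = []
    ainv_cache = None
    for name, column, kind in spec.random_terms:
        if kind.startswith("pedigree"):
            if pedigree is None:
                raise MixedModelError(f"random term {name!r} needs a pedigree")
            if ainv_cache is None:
                ainv_cache = a_inverse(pedigree, use_upg=use_upg)
            Ainv, groups = ainv_cache
            levels = list(pedigree.individuals) + list(groups)
            Z = incidence(data[column].astype(str), levels)
            lu = splu(Ainv.tocsc())
            logdet_ainv = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
            terms.append(
                RandomTerm(name, Z, kinv=Ainv, logdet_k=-logdet_ainv, levels=levels)
            )
        else:
            levels = list(dict.fromkeys(data[column].astype(str)))
            Z = incidence(data[column].astype(str), levels)
            terms.append(RandomTerm(name, Z, kinv=None, logdet_k=0.0, levels=levels))
    return y, X, labels, terms, dropped


def _drop_aliased(X: np.ndarray, labels: list) -> tuple[np.ndarray, list, list]:
    """Drop linearly dependent columns (QR with column pivoting)."""
    if X.shape[1] == 0:
        return X, labels, []
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int(np.sum(diag > tol))
    keep = sorted(piv[:rank])
    dropped = [labels[j] for j in range(X.shape[1]) if j not in keep]
    return X[:, keep], [labels[j] for j in keep], dropped


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------

class _MME:
    """Henderson's MME for given variance components.

    C = W'W / s2e + blockdiag(0, Kinv_i / s2_i); rhs = W'y / s2e.
    C^{-1} is directly the covariance matrix of (BLUE, u_hat - u).
    """

    def __init__(self, y, X, terms, sigma2: dict, kinv_joint=None):
        self.y = y
        self.X = X
        self.terms = terms
        self.n, self.p = X.shape
        self.q = [t.n_levels for t in terms]
        self.sigma2 = dict(sigma2)
        W = sparse.hstack([sparse.csr_matrix(X)] + [t.Z for t in terms]).tocsr()
        self.W = W
        s2e = sigma2["residual"]
        C = (W.T @ W) / s2e
        offset = self.p
        if kinv_joint is not None:
            # pre-scaled joint inverse covariance across all random levels
            C = C + sparse.block_diag(
                [sparse.csr_matrix((self.p, self.p)), kinv_joint]
            )
        else:
            blocks = [sparse.csr_matrix((self.p, self.p))]
            for t in terms:
                ki = t.kinv if t.kinv is not None else sparse.identity(t.n_levels, format="csr")
                blocks.append(ki / sigma2[t.name])
            C = C + sparse.block_diag(blocks)
        self.C = C.tocsc()
        self.rhs = np.asarray(W.T @ y).ravel() / s2e
        self.lu = splu(self.C)
        self.sol = self.lu.solve(self.rhs)
        self.offset = offset

    @property
    def beta(self):
        return self.sol[: self.p]

    def u(self, i: int):
        start = self.p + sum(self.q[:i])
        return self.sol[start : start + self.q[i]]

    @property
    def residuals(self):
        return self.y - np.asarray(self.W @ self.sol).ravel()

    def logdet_C(self) -> float:
        return float(np.sum(np.log(np.abs(self.lu.U.diagonal()))))

    def yPy(self) -> float:
        return float(self.y @ self.y / self.sigma2["residual"] - self.sol @ self.rhs)

    def Pv(self, v: np.ndarray) -> np.ndarray:
        """P v where P = V^{-1} - V^{-1}X(X'V^{-1}X)^{-1}X'V^{-1}."""
        rhs = np.asarray(self.W.T @ v).ravel() / self.sigma2["residual"]
        sol = self.lu.solve(rhs)
        return (v - np.asarray(self.W @ sol).ravel()) / self.sigma2["residual"]


def _minus2_reml_loglik(y, X, terms, sigma2: dict) -> float:
    mme = _MME(y, X, terms, sigma2)
    n, p = X.shape
    val = n * np.log(sigma2["residual"])
    for t in terms:
        val += t.n_levels * np.log(sigma2[t.name]) + t.logdet_k
    val += mme.logdet_C() + mme.yPy()
    return float(val)


def reml(
    y,
    X,
    terms,
    init: dict | None = None,
    tol: float = 1e-6,
    max_rounds: int = 100,
) -> tuple[VarianceComponents, dict]:
    """Average-information REML with EM fallback.

    Scores are central finite differences of the exact restricted
    log-likelihood (each evaluation is one sparse factorisation); the AI
    matrix uses the standard working variates f_i = Z_i u_hat_i / sigma2_i and
    f_e = Py.  When an AI step leaves the parameter space an EM step is taken
    instead; estimates hitting the floor are clamped and flagged.

    Returns the components and an info dict (converged, rounds, trace,
    boundary flags).
    """
    names = [t.name for t in terms] + ["residual"]
    vy = float(np.var(y)) if np.var(y) > 0 else 1.0
    floor = 1e-8 * vy
    if init is None:
        k = len(terms) + 1
        theta = np.full(len(names), vy / k)
    else:
        theta = np.array([init[n] for n in names], dtype=float)
    if np.any(theta <= 0):
        raise MixedModelError("initial variance components must be positive")

    def loglik(th):
        return -0.5 * _minus2_reml_loglik(y, X, terms, dict(zip(names, th)))

    trace = []
    boundary = [False] * len(names)
    converged = False
    ll = loglik(theta)
    for rnd in range(1, max_rounds + 1):
        sigma2 = dict(zip(names, theta))
        mme = _MME(y, X, terms, sigma2)
        Py = mme.residuals / sigma2["residual"]
        fs = [
            np.asarray(terms[i].Z @ mme.u(i)).ravel() / sigma2[terms[i].name]
            for i in range(len(terms))
        ] + [Py]
        Pfs = [mme.Pv(f) for f in fs]
        k = len(names)
        AI = np.empty((k, k))
        for a in range(k):
            for b in range(a, k):
                AI[a, b] = AI[b, a] = 0.5 * float(fs[a] @ Pfs[b])
        # finite-difference score of the exact restricted log-likelihood
        score = np.empty(k)
        for a in range(k):
            h = max(1e-4 * theta[a], 1e-10)
            tp, tm = theta.copy(), theta.copy()
            tp[a] += h
            tm[a] = max(tm[a] - h, floor * 0.5)
            score[a] = (loglik(tp) - loglik(tm)) / (tp[a] - tm[a])
        try:
            step = np.linalg.solve(AI + 1e-10 * np.eye(k), score)
        except np.linalg.LinAlgError:
            step = score / np.maximum(np.diag(AI), 1e-12)
        # clamp components the AI step pushes out of the parameter space
        new = np.maximum(theta + step, floor)
        used = "AI"
        ll_new = loglik(new)
        if ll_new < ll - 1e-10:
            new = np.maximum(_em_step(mme, terms, sigma2, X, floor), floor)
            used = "EM"
            ll_new = loglik(new)
        at_floor = new <= floor * 1.0001
        rel = np.max(
            np.where(
                at_floor & (theta <= floor * 1.0001),
                0.0,  # a component parked at the floor has converged
                np.abs(new - theta) / np.maximum(theta, floor),
            )
        )
        trace.append({"round": rnd, "theta": theta.copy(), "loglik": ll, "step": used})
        theta = new
        ll = ll_new
        if rel < tol or (rnd > 5 and abs(ll - trace[-1]["loglik"]) < 1e-10):
            converged = True
            break
    boundary = [bool(v <= floor * 1.0001) for v in theta]
    if any(boundary):
        logger.warning(
            "variance components at floor: %s",
            [n for n, b in zip(names, boundary) if b],
        )
    if not converged:
        raise MixedModelError(
            f"REML did not converge in {max_rounds} rounds; trace: "
            + "; ".join(f"r{t['round']} {t['step']} ll={t['loglik']:.4f}" for t in trace[-5:])
        )
    info = {"converged": converged, "rounds": rnd, "trace": trace, "boundary": dict(zip(names, boundary))}
    return VarianceComponents(dict(zip(names, theta))), info


def _em_step(mme: _MME, terms, sigma2: dict, X, floor) -> np.ndarray:
    """Classical EM-REML update; needs diagonal blocks of C^{-1} (selected
    column solves against the cached factorisation)."""
    out = []
    for i, t in enumerate(terms):
        u = mme.u(i)
        q = t.n_levels
        start = mme.p + sum(mme.q[:i])
        # trace(Kinv @ Cinv_block)
        tr = 0.0
        ki = t.kinv if t.kinv is not None else sparse.identity(q, format="csr")
        for j in range(q):
            e = np.zeros(mme.C.shape[0])
            e[start + j] = 1.0
            col = mme.lu.solve(e)
            tr += float(np.asarray(ki[j, :] @ col[start : start + q]).ravel()[0])
        uku = float(u @ (ki @ u))
        out.append(max((uku + tr) / q, floor))
    n, p = X.shape
    resid = mme.residuals
    s2e = float(resid @ mme.y) / (n - p)
    out.append(max(s2e, floor))
    return np.array(out)


def solve_blup(
    y,
    X,
    terms,
    varcomp: VarianceComponents,
    fixed_labels=None,
    kinv_joint=None,
) -> MixedModelFit:
    """Solve Henderson's MME at the given variance components.

    ``kinv_joint`` supports correlated random effects (e.g. maternal +
    direct sharing A with a 2x2 genetic covariance): pass the pre-scaled
    joint inverse covariance of the stacked random levels.
    """
    for name, v in varcomp.values.items():
        if v < 0:
            raise MixedModelError(f"negative variance for {name!r}")
    mme = _MME(y, X, terms, varcomp.values, kinv_joint=kinv_joint)
    random_solutions = {}
    for i, t in enumerate(terms):
        random_solutions[t.name] = (list(t.levels), mme.u(i))
    fit = MixedModelFit(
        varcomp=varcomp,
        fixed_labels=list(fixed_labels) if fixed_labels is not None else [f"b{j}" for j in range(X.shape[1])],
        fixed_solutions=mme.beta,
        random_solutions=random_solutions,
        residuals=mme.residuals,
        fitted=np.asarray(mme.W @ mme.sol).ravel(),
        y=y,
        n_fixed=X.shape[1],
    )
    fit._cov_solver = mme.lu
    return fit


# ---------------------------------------------------------------------------
# maternal-direct stillbirth model
# ---------------------------------------------------------------------------

def maternal_direct_kinv(
    ainv: sparse.spmatrix,
    s2_m: float,
    s2_u: float,
    cov_mu: float,
) -> sparse.csr_matrix:
    """Joint inverse covariance G0^{-1} (x) A^{-1} for the stacked
    (maternal, direct) random effects."""
    G0 = np.array([[s2_m, cov_mu], [cov_mu, s2_u]])
    det = np.linalg.det(G0)
    if det <= 0:
        raise MixedModelError("direct-maternal covariance matrix not positive definite")
    G0i = np.linalg.inv(G0)
    return sparse.kron(sparse.csr_matrix(G0i), ainv, format="csr")


def fit_stillbirth_group(
    records: pd.DataFrame,
    pedigree,
    varcomp: dict,
    with_pe: bool,
    fixed_terms=None,
    use_upg: bool = False,
) -> MixedModelFit:
    """Maternal-direct animal model for one parity group of calving records.

    Records need columns: value (0 dead / 1 live), calf, dam, plus the fixed
    covariate columns.  Random structure: maternal (dam) + direct (calf)
    genetic effects over the pedigree with covariance, herd-year, and a dam
    permanent-environment term for the later-parity group.
    """
    if fixed_terms is None:
        fixed_terms = [t for t in ("h5y", "age_of_dam", "month", "calf_sex") if t in records.columns]
    spec = ModelSpec(response="value", fixed_terms=fixed_terms, random_terms=[])
    y, X, labels, _, dropped = build_design(records, spec)

    Ainv, groups = a_inverse(pedigree, use_upg=use_upg)
    levels = list(pedigree.individuals) + list(groups)
    Zm = incidence(records["dam"].astype(str), levels)
    Zu = incidence(records["calf"].astype(str), levels)
    terms = [
        RandomTerm("maternal", Zm, kinv=None, levels=levels),
        RandomTerm("direct", Zu, kinv=None, levels=levels),
    ]
    kj = maternal_direct_kinv(
        Ainv, varcomp["maternal"], varcomp["direct"], varcomp.get("cov_direct_maternal", 0.0)
    )
    blocks = [kj]
    if "hy" in records.columns:
        hy_levels = list(dict.fromkeys(records["hy"].astype(str)))
        Zhy = incidence(records["hy"].astype(str), hy_levels)
        terms.append(RandomTerm("hy", Zhy, kinv=None, levels=hy_levels))
        blocks.append(sparse.identity(len(hy_levels), format="csr") / varcomp["hy"])
    if with_pe:
        pe_levels = list(dict.fromkeys(records["dam"].astype(str)))
        Zpe = incidence(records["dam"].astype(str), pe_levels)
        terms.append(RandomTerm("pe", Zpe, kinv=None, levels=pe_levels))
        blocks.append(sparse.identity(len(pe_levels), format="csr") / varcomp["pe"])
    kinv_joint = sparse.block_diag(blocks, format="csr")
    vc = VarianceComponents(
        {**{t.name: varcomp.get(t.name, 1.0) for t in terms}, "residual": varcomp["residual"]},
        cov_direct_maternal=varcomp.get("cov_direct_maternal", 0.0),
    )
    fit = solve_blup(y, X, terms, vc, fixed_labels=labels, kinv_joint=kinv_joint)
    fit.dropped_fixed = dropped
    return fit


# ---------------------------------------------------------------------------
# corrected phenotypes
# ---------------------------------------------------------------------------

def corrected_phenotypes_stillbirth(
    fit_first: MixedModelFit,
    records_first: pd.DataFrame,
    fit_later: MixedModelFit | None = None,
    records_later: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Environment-corrected stillbirth phenotypes.

    DSB1: dam's maternal EBV + residual of her (single) first-parity record.
    SSB1: calf's direct EBV + residual of its own birth record.
    DSB2: dam's maternal EBV + PE + mean residual over her later records.
    SSB2: calf's direct EBV + residual of its own (later-parity) birth record.
    Animals with an EBV but no own record are excluded and counted in the log.
    """
    out = []
    skipped = 0

    def ebv(fit, term, animal):
        levels, values = fit.random_solutions[term]
        try:
            return float(values[levels.index(animal)])
        except ValueError:
            return None

    resid1 = pd.Series(fit_first.residuals, index=records_first.index)
    by_dam1 = {d: i for i, d in zip(records_first.index, records_first["dam"])}
    for dam, ridx in by_dam1.items():
        e = ebv(fit_first, "maternal", dam)
        if e is None:
            skipped += 1
            continue
        out.append((dam, "DSB1", e + float(resid1[ridx])))
    for ridx, calf in zip(records_first.index, records_first["calf"]):
        e = ebv(fit_first, "direct", calf)
        if e is None:
            skipped += 1
            continue
        out.append((calf, "SSB1", e + float(resid1[ridx])))

    if fit_later is not None and records_later is not None:
        resid2 = pd.Series(fit_later.residuals, index=records_later.index)
        pe_levels, pe_values = fit_later.random_solutions.get("pe", ([], np.array([])))
        pe_lut = dict(zip(pe_levels, pe_values))
        for dam, grp in records_later.groupby("dam"):
            e = ebv(fit_later, "maternal", dam)
            if e is None:
                skipped += 1
                continue
            pe = float(pe_lut.get(dam, 0.0))
            out.append((dam, "DSB2", e + pe + float(resid2[grp.index].mean())))
        for ridx, calf in zip(records_later.index, records_later["calf"]):
            e = ebv(fit_later, "direct", calf)
            if e is None:
                skipped += 1
                continue
            out.append((calf, "SSB2", e + float(resid2[ridx])))
    if skipped:
        logger.info("corrected phenotypes: %d animals without own record excluded", skipped)
    return pd.DataFrame(out, columns=["animal", "trait", "y_star"])


def corrected_phenotypes_repeatability(
    fit: MixedModelFit,
    records: pd.DataFrame,
    animal_column: str,
    trait: str,
    genetic_term: str = "animal",
    pe_term: str = "pe",
) -> pd.DataFrame:
    """y* = EBV + PE + mean residual over the animal's records."""
    levels, values = fit.random_solutions[genetic_term]
    lut = dict(zip(levels, values))
    pe_levels, pe_values = fit.random_solutions.get(pe_term, ([], np.array([])))
    pe_lut = dict(zip(pe_levels, pe_values))
    resid = pd.Series(fit.residuals, index=records.index)
    out = []
    skipped = 0
    for animal, grp in records.groupby(animal_column):
        if animal not in lut:
            skipped += 1
            continue
        y_star = float(lut[animal]) + float(pe_lut.get(animal, 0.0)) + float(resid[grp.index].mean())
        out.append((animal, trait, y_star))
    if skipped:
        logger.info("corrected phenotypes (%s): %d animals skipped", trait, skipped)
    return pd.DataFrame(out, columns=["animal", "trait", "y_star"])


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

def heritability(varcomp: dict, which: str) -> float:
    """Heritability on the observed scale.

    ``which``: "maternal" or "direct" for the maternal-direct model
    (shared denominator s2m + s2u + s2e + 2*cov); "repeatability" for
    s2u / (s2u + s2pe + s2e).
    """
    if which in ("maternal", "direct"):
        s2m = varcomp["maternal"]
        s2u = varcomp["direct"]
        s2e = varcomp["residual"]
        cov = varcomp.get("cov_direct_maternal", 0.0)
        denom = s2m + s2u + s2e + 2.0 * cov
        if denom <= 0:
            raise MixedModelError("non-positive heritability denominator")
        return (s2m if which == "maternal" else s2u) / denom
    if which == "repeatability":
        s2u = varcomp["animal"]
        denom = s2u + varcomp.get("pe", 0.0) + varcomp["residual"]
        if denom <= 0:
            raise MixedModelError("non-positive heritability denominator")
        return s2u / denom
    raise ValueError(f"unknown heritability kind {which!r}")
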