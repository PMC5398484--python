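"""Matrix-variate linear mixed model with Kronecker-structured covariance.

For a complete design the N x C phenotype matrix Y is modelled as

    vec(Y) ~ N( vec(F B),  Cs (x) Rs + Cn (x) I_N )

where Rs = G G^T / S is the local realized relatedness matrix of the S
standardized region variants, Cs is the C x C trait-context covariance of
the set component and Cn the residual trait-context covariance.  Structural
constraints on Cs (null / block / rank-one / full) correspond one-to-one to
persistent, rescaling and heterogeneous genetic architectures across
contexts.

The restricted (REML) log-likelihood is evaluated on an efficient path:

* complete design — a one-off eigendecomposition of Rs turns every
  evaluation into C independent diagonal generalized-least-squares
  problems, linear in N;
* stratified design (one observed context per individual) — the covariance
  is low-rank (<= C*S) plus diagonal; Woodbury identities on per-context
  Gram matrices make evaluations O(S^2 C^2) after a one-off precompute.

A dense oracle builds the full covariance explicitly and serves as the
independent reference in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = [
    "RegionGenotypes",
    "StudyDesign",
    "TraitContextCovariance",
    "FittedModel",
    "materialize",
    "reml_objective",
    "dense_oracle",
    "fit",
    "KroneckerSetLMM",
    "sample_phenotypes",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class RegionGenotypes:
    """Standardized dosages for a testing region and the derived kernel.

    G has per-variant mean 0 and variance 1; Rs = G G^T / S so the mean of
    its diagonal is exactly 1.
    """

    G: np.ndarray
    variant_ids: np.ndarray | None = None
    positions: np.ndarray | None = None
    chrom: str = "1"
    Rs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.G = np.ascontiguousarray(self.G, dtype=float)
        if self.G.ndim != 2 or self.G.shape[1] < 1:
            raise ValueError("G must be N x S with S >= 1")
        self.Rs = self.G @ self.G.T / self.G.shape[1]
        self._eig = None

    @property
    def n_individuals(self) -> int:
        return self.G.shape[0]

    @property
    def n_variants(self) -> int:
        return self.G.shape[1]

    def eig(self):
        """Cached eigendecomposition of Rs (one-off per region).

        When S < N the spectrum is obtained from the SVD of G (cost O(N S^2))
        and completed with an orthonormal null-space basis; otherwise a
        sample-space eigendecomposition of Rs is used.
        """
        if self._eig is None:
            N, S = self.G.shape
            if S < N // 2:
                U_g, sv, _ = sla.svd(self.G, full_matrices=True, lapack_driver="gesdd")
                lam = np.zeros(N)
                lam[: sv.size] = sv**2 / S
                self._eig = (np.maximum(lam, 0.0), U_g)
            else:
                lam, U = sla.eigh(self.Rs)
                self._eig = (np.maximum(lam[::-1], 0.0), U[:, ::-1])
        return self._eig


@dataclass
class StudyDesign:
    """Phenotypes plus fixed-effect covariates.

    Complete layout: ``Y`` is N x C (every individual measured in every
    context).  Stratified layout: ``y`` is length N with one observed value
    per individual and ``contexts`` gives the observed context label.
    ``F`` holds fixed-effect covariates (intercept, measured covariates,
    principal components); it may have zero columns.
    """

    layout: str
    Y: np.ndarray | None = None
    y: np.ndarray | None = None
    contexts: np.ndarray | None = None
    F: np.ndarray | None = None
    n_contexts: int | None = None

    def __post_init__(self) -> None:
        if self.layout not in ("complete", "stratified"):
            raise ValueError("layout must be 'complete' or 'stratified'")
        if self.layout == "complete":
            if self.Y is None:
                raise ValueError("complete design requires Y")
            self.Y = np.asarray(self.Y, dtype=float)
            if self.Y.ndim != 2:
                raise ValueError("Y must be N x C")
            if not np.isfinite(self.Y).all():
                raise ValueError("Y contains missing/non-finite values")
            n, c = self.Y.shape
            self.n_contexts = c
        else:
            if self.y is None or self.contexts is None:
                raise ValueError("stratified design requires y and contexts")
            self.y = np.asarray(self.y, dtype=float).ravel()
            self.contexts = np.asarray(self.contexts, dtype=int).ravel()
            if self.y.shape != self.contexts.shape:
                raise ValueError("y and contexts must have equal length")
            if not np.isfinite(self.y).all():
                raise ValueError("y contains missing/non-finite values")
            n = self.y.size
            if self.n_contexts is None:
                self.n_contexts = int(self.contexts.max()) + 1
            counts = np.bincount(self.contexts, minlength=self.n_contexts)
            if (counts < 2).any():
                raise ValueError("every context needs >= 2 individuals")
        if self.F is None:
            self.F = np.empty((n, 0))
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape[0] != n:
            raise ValueError("F row count must match sample count")
        if self.F.shape[1] and np.linalg.matrix_rank(self.F) < self.F.shape[1]:
            raise ValueError("F must have full column rank")

    @property
    def n_individuals(self) -> int:
        return self.Y.shape[0] if self.layout == "complete" else self.y.size


# ---------------------------------------------------------------------------
# Trait-context covariance structures
# ---------------------------------------------------------------------------

_KINDS = ("null", "block", "rank1", "full")


def n_params(kind: str, C: int) -> int:
    if kind == "null":
        return 0
    if kind == "block":
        return 1
    if kind == "rank1":
        return C
    if kind == "full":
        return C * (C + 1) // 2
    raise ValueError(f"unknown covariance kind {kind!r}")


def _tril_indices(C):
    return np.tril_indices(C)


@dataclass
class TraitContextCovariance:
    """A C x C set-component covariance with a structural kind.

    Parametrizations keep the matrix PSD for any real parameter vector:
    block Cs = theta^2 * 1, rank-one Cs = a a^T, full Cs = A A^T with A
    lower-triangular, null Cs = 0.
    """

    kind: str
    C: int

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")

    @property
    def n_free(self) -> int:
        return n_params(self.kind, self.C)

    def materialize(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.size != self.n_free:
            raise ValueError(
                f"kind {self.kind!r} expects {self.n_free} parameters, got {theta.size}"
            )
        C = self.C
        if self.kind == "null":
            return np.zeros((C, C))
        if self.kind == "block":
            return theta[0] ** 2 * np.ones((C, C))
        if self.kind == "rank1":
            return np.outer(theta, theta)
        A = np.zeros((C, C))
        A[_tril_indices(C)] = theta
        return A @ A.T

    def grads(self, theta):
        """d Cs / d theta_p for each free parameter."""
        theta = np.asarray(theta, dtype=float).ravel()
        C = self.C
        out = []
        if self.kind == "null":
            return out
        if self.kind == "block":
            out.append(2.0 * theta[0] * np.ones((C, C)))
            return out
        if self.kind == "rank1":
            for i in range(C):
                d = np.zeros((C, C))
                d[i, :] += theta
                d[:, i] += theta
                out.append(d)
            return out
        A = np.zeros((C, C))
        rows, cols = _tril_indices(C)
        A[rows, cols] = theta
        for r, c in zip(rows, cols):
            E = np.zeros((C, C))
            E[r, c] = 1.0
            out.append(E @ A.T + A @ E.T)
        return out


class _NoiseCov:
    """Cn via a lower-triangular factor with exponentiated diagonal.

    Complete designs use a full lower-triangular factor (C(C+1)/2 free
    parameters); stratified designs restrict Cn to its diagonal (C free
    parameters) because off-diagonal entries never enter the likelihood.
    """

    def __init__(self, C: int, diagonal: bool = False):
        self.C = C
        self.diagonal = diagonal
        self.n_free = C if diagonal else C * (C + 1) // 2

    def factor(self, theta):
        theta = np.asarray(theta, dtype=float).ravel()
        C = self.C
        L = np.zeros((C, C))
        if self.diagonal:
            L[np.diag_indices(C)] = np.exp(np.clip(theta, -15, 15))
            return L
        rows, cols = _tril_indices(C)
        L[rows, cols] = theta
        d = np.clip(np.diag(L).copy(), -15, 15)
        L[np.diag_indices(C)] = np.exp(d)
        return L

    def materialize(self, theta):
        L = self.factor(theta)
        return L @ L.T

    def grads(self, theta):
        theta = np.asarray(theta, dtype=float).ravel()
        C = self.C
        L = self.factor(theta)
        out = []
        if self.diagonal:
            for i in range(C):
                dL = np.zeros((C, C))
                dL[i, i] = L[i, i]
                out.append(dL @ L.T + L @ dL.T)
            return out
        rows, cols = _tril_indices(C)
        for r, c in zip(rows, cols):
            dL = np.zeros((C, C))
            dL[r, c] = L[r, r] if r == c else 1.0
            out.append(dL @ L.T + L @ dL.T)
        return out


def materialize(cov: TraitContextCovariance, theta) -> np.ndarray:
    """Materialize a trait-context covariance from its free parameters."""
    return cov.materialize(theta)


# ---------------------------------------------------------------------------
# Efficient REML objective
# ---------------------------------------------------------------------------


class _CompleteWorkspace:
    """Per-(design, region) precompute for the complete-design fast path."""

    def __init__(self, design: StudyDesign, region: RegionGenotypes):
        if region.n_individuals != design.n_individuals:
            raise ValueError("design and region must share individual ordering")
        lam, U = region.eig()
        self.lam = lam
        self.Yt = U.T @ design.Y
        self.Ft = U.T @ design.F
        self.N, self.C = design.Y.shape
        self.K = design.F.shape[1]

    def nll_parts(self, Cs, Cn):
        """Return (nll, cache) for gradient reuse; raises on singular Cn."""
        N, C, K = self.N, self.C, self.K
        try:
            E = sla.cholesky(Cn, lower=True)
        except sla.LinAlgError as exc:
            raise FloatingPointError("singular or indefinite Cn") from exc
        Ei = sla.solve_triangular(E, np.eye(C), lower=True)
        A = Ei @ Cs @ Ei.T
        d, Q = sla.eigh(A)
        d = np.maximum(d, 0.0)
        M = Ei.T @ Q  # transform: Ytil = Yt @ M
        s = np.outer(self.lam, d) + 1.0  # N x C
        logdet_cn = 2.0 * np.sum(np.log(np.diag(E)))
        logdetV = np.sum(np.log(s)) + N * logdet_cn

        Ytil = self.Yt @ M
        W = 1.0 / s
        quad = 0.0
        logdetXVX = 0.0
        rtil = np.empty_like(Ytil)
        Ainvs = []
        if K:
            for c in range(C):
                WF = W[:, c, None] * self.Ft
                Ac = self.Ft.T @ WF
                cho = sla.cho_factor(Ac, lower=True)
                beta = sla.cho_solve(cho, WF.T @ Ytil[:, c])
                rtil[:, c] = Ytil[:, c] - self.Ft @ beta
                quad += float(rtil[:, c] @ (W[:, c] * rtil[:, c]))
                logdetXVX += 2.0 * np.sum(np.log(np.diag(cho[0])))
                Ainvs.append(sla.cho_solve(cho, np.eye(K)))
            logdetXVX -= K * logdet_cn
        else:
            rtil[:] = Ytil
            quad = float(np.sum(W * Ytil**2))
        nll = 0.5 * (logdetV + logdetXVX + quad + (N - K) * C * _LOG2PI)
        cache = dict(M=M, W=W, rtil=rtil, Ainvs=Ainvs, lam=self.lam)
        return nll, cache

    def gradient(self, cache, dCs_list, dCn_list):
        """Analytic REML gradient for the complete design.

        For each parameter with direction dV = dCs (x) Rs + dCn (x) I,
        d nll / d theta = 0.5 * [ tr(V^-1 dV) - tr((X'V^-1X)^-1 X'V^-1 dV V^-1 X)
                                  - (V^-1 r)' dV (V^-1 r) ].
        All traces reduce to diagonal sums in the transformed basis.
        """
        M, W, rtil, Ainvs, lam = (
            cache["M"],
            cache["W"],
            cache["rtil"],
            cache["Ainvs"],
            cache["lam"],
        )
        C, K = self.C, self.K
        w = W * rtil  # transformed V^-1 r
        lam_w = lam[:, None] * w
        grads = []
        for dCs, dCn in zip(dCs_list, dCn_list):
            Phi = M.T @ dCs @ M if dCs is not None else None
            Phin = M.T @ dCn @ M if dCn is not None else None
            g = 0.0
            # tr(V^-1 dV)
            for c in range(C):
                coef_s = Phi[c, c] if Phi is not None else 0.0
                coef_n = Phin[c, c] if Phin is not None else 0.0
                if coef_s:
                    g += coef_s * float(np.sum(lam * W[:, c]))
                if coef_n:
                    g += coef_n * float(np.sum(W[:, c]))
            # REML correction: - tr((XVX)^-1 X V^-1 dV V^-1 X)
            if K:
                for c in range(C):
                    coef_s = Phi[c, c] if Phi is not None else 0.0
                    coef_n = Phin[c, c] if Phin is not None else 0.0
                    if coef_s == 0.0 and coef_n == 0.0:
                        continue
                    diag = (coef_s * lam + coef_n) * W[:, c] ** 2
                    Nc = self.Ft.T @ (diag[:, None] * self.Ft)
                    g -= float(np.sum(Ainvs[c] * Nc))
            # quadratic form: - w' dV~ w
            if Phi is not None:
                g -= float(np.einsum("ic,cd,id->", lam_w, Phi, w, optimize=True))
            if Phin is not None:
                g -= float(np.einsum("ic,cd,id->", w, Phin, w, optimize=True))
            grads.append(0.5 * g)
        return np.array(grads)


class _StratifiedWorkspace:
    """Per-(design, region) Gram precompute for the stratified fast path.

    V = Z Z^T + Delta with Z[:, kS:(k+1)S] = diag(Ls[c_i, k]) G / sqrt(S) and
    Delta_ii = Cn[c_i, c_i]; all Woodbury products reduce to per-context Gram
    matrices G_a^T G_a, F_a^T G_a, ... computed once.
    """

    def __init__(self, design: StudyDesign, region: RegionGenotypes):
        if region.n_individuals != design.n_individuals:
            raise ValueError("design and region must share individual ordering")
        self.C = design.n_contexts
        self.K = design.F.shape[1]
        self.N = design.n_individuals
        self.S = region.n_variants
        G = region.G / np.sqrt(self.S)
        y, ctx, F = design.y, design.contexts, design.F
        self.GtG, self.FtG, self.Fty, self.Gty, self.yty, self.FtF, self.navec = (
            [], [], [], [], [], [], [],
        )
        for a in range(self.C):
            m = ctx == a
            Ga, Fa, ya = G[m], F[m], y[m]
            self.GtG.append(Ga.T @ Ga)
            self.FtG.append(Fa.T @ Ga)
            self.Fty.append(Fa.T @ ya)
            self.Gty.append(Ga.T @ ya)
            self.yty.append(float(ya @ ya))
            self.FtF.append(Fa.T @ Fa)
            self.navec.append(int(m.sum()))

    def nll(self, Cs, Cn):
        C, K, N, S = self.C, self.K, self.N, self.S
        dn = np.diag(Cn).copy()
        if np.any(dn <= 0) or not np.all(np.isfinite(dn)):
            raise FloatingPointError("stratified Cn diagonal must be positive")
        # PSD factor of Cs
        dcs, Qcs = sla.eigh(Cs)
        dcs = np.maximum(dcs, 0.0)
        Ls = Qcs * np.sqrt(dcs)  # Cs = Ls Ls^T
        R = Ls.shape[1]  # = C columns
        CS = R * S  # latent dimension of Z

        # A_w = I + Z' Delta^-1 Z, assembled from per-context Grams
        Aw = np.eye(CS)
        ZtDy = np.zeros(CS)
        ZtDX = np.zeros((CS, K * C))
        XtDX = np.zeros((K * C, K * C))
        XtDy = np.zeros(K * C)
        ytDy = 0.0
        logdetDelta = 0.0
        for a in range(C):
            inv = 1.0 / dn[a]
            logdetDelta += self.navec[a] * np.log(dn[a])
            ytDy += inv * self.yty[a]
            for k in range(R):
                lk = Ls[a, k]
                ZtDy[k * S : (k + 1) * S] += inv * lk * self.Gty[a]
                if K:
                    ZtDX[k * S : (k + 1) * S, a * K : (a + 1) * K] += (
                        inv * lk * self.FtG[a].T
                    )
                for k2 in range(R):
                    Aw[k * S : (k + 1) * S, k2 * S : (k2 + 1) * S] += (
                        inv * lk * Ls[a, k2]
                    ) * self.GtG[a]
            if K:
                XtDX[a * K : (a + 1) * K, a * K : (a + 1) * K] = inv * self.FtF[a]
                XtDy[a * K : (a + 1) * K] = inv * self.Fty[a]

        cho = sla.cho_factor(Aw, lower=True)
        logdetV = 2.0 * np.sum(np.log(np.diag(cho[0]))) + logdetDelta

        Ainv_Zy = sla.cho_solve(cho, ZtDy)
        ytVy = ytDy - float(ZtDy @ Ainv_Zy)
        if K:
            Ainv_ZX = sla.cho_solve(cho, ZtDX)
            XtVX = XtDX - ZtDX.T @ Ainv_ZX
            XtVy = XtDy - ZtDX.T @ Ainv_Zy
            cx = sla.cho_factor(XtVX, lower=True)
            beta = sla.cho_solve(cx, XtVy)
            quad = ytVy - float(beta @ XtVy)
            logdetXVX = 2.0 * np.sum(np.log(np.diag(cx[0])))
            p = K * C
        else:
            quad = ytVy
            logdetXVX = 0.0
            p = 0
        return 0.5 * (logdetV + logdetXVX + quad + (N - p) * _LOG2PI)


def _as_cov(cov_kind: str, C: int) -> TraitContextCovariance:
    return TraitContextCovariance(cov_kind, C)


def reml_objective(
    design: StudyDesign,
    region: RegionGenotypes,
    cov_kind: str,
    theta_s,
    theta_n,
    workspace=None,
    with_grad: bool = False,
):
    """Negative restricted log-likelihood on the efficient path.

    ``theta_s`` parametrizes Cs under ``cov_kind``; ``theta_n`` parametrizes
    Cn (lower-triangular factor with exponentiated diagonal; diagonal-only in
    stratified designs).  With ``with_grad=True`` (complete designs only) the
    analytic gradient with respect to (theta_s, theta_n) is also returned.
    """
    theta_s = np.asarray(theta_s, dtype=float).ravel()
    theta_n = np.asarray(theta_n, dtype=float).ravel()
    if not (np.isfinite(theta_s).all() and np.isfinite(theta_n).all()):
        raise ValueError("non-finite parameters")
    C = design.n_contexts
    cov = _as_cov(cov_kind, C)
    Cs = cov.materialize(theta_s)
    noise = _NoiseCov(C, diagonal=design.layout == "stratified")
    Cn = noise.materialize(theta_n)
    if design.layout == "complete":
        ws = workspace or _CompleteWorkspace(design, region)
        nll, cache = ws.nll_parts(Cs, Cn)
        if not with_grad:
            return nll
        dCs_list = cov.grads(theta_s)
        dCn_list = noise.grads(theta_n)
        dirs_s = [(d, None) for d in dCs_list]
        dirs_n = [(None, d) for d in dCn_list]
        g = ws.gradient(
            cache,
            [a for a, _ in dirs_s + dirs_n],
            [b for _, b in dirs_s + dirs_n],
        )
        return nll, g
    ws = workspace or _StratifiedWorkspace(design, region)
    nll = ws.nll(Cs, Cn)
    if with_grad:
        raise NotImplementedError("analytic gradient is complete-design only")
    return nll


def dense_oracle(design: StudyDesign, region: RegionGenotypes, cov_kind, theta_s, theta_n):
    """Reference REML objective via the explicit full covariance matrix.

    Guarded to small problems (N*C <= 500); used as the independent check of
    the efficient path.
    """
    C = design.n_contexts
    N = design.n_individuals
    if N * C > 500:
        raise ValueError("dense oracle limited to N*C <= 500")
    cov = _as_cov(cov_kind, C)
    Cs = cov.materialize(np.asarray(theta_s, dtype=float))
    noise = _NoiseCov(C, diagonal=design.layout == "stratified")
    Cn = noise.materialize(np.asarray(theta_n, dtype=float))
    Rs = region.Rs
    if design.layout == "complete":
        V = np.kron(Cs, Rs) + np.kron(Cn, np.eye(N))
        yv = design.Y.T.ravel()  # vec by stacking columns (context-major)
        X = np.kron(np.eye(C), design.F) if design.F.shape[1] else np.empty((N * C, 0))
    else:
        ctx = design.contexts
        V = Cs[np.ix_(ctx, ctx)] * Rs + np.diag(np.diag(Cn)[ctx])
        yv = design.y
        K = design.F.shape[1]
        if K:
            X = np.zeros((N, K * C))
            for a in range(C):
                m = ctx == a
                X[m, a * K : (a + 1) * K] = design.F[m]
        else:
            X = np.empty((N, 0))
    n = yv.size
    p = X.shape[1]
    cho = sla.cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Vi_y = sla.cho_solve(cho, yv)
    if p:
        Vi_X = sla.cho_solve(cho, X)
        XtVX = X.T @ Vi_X
        cx = sla.cho_factor(XtVX, lower=True)
        beta = sla.cho_solve(cx, X.T @ Vi_y)
        r = yv - X @ beta
        Vi_r = sla.cho_solve(cho, r)
        quad = float(r @ Vi_r)
        logdetXVX = 2.0 * np.sum(np.log(np.diag(cx[0])))
    else:
        quad = float(yv @ Vi_y)
        logdetXVX = 0.0
    return 0.5 * (logdetV + logdetXVX + quad + (n - p) * _LOG2PI)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """REML estimate of a constrained trait-context covariance model."""

    cov_kind: str
    Cs: np.ndarray
    Cn: np.ndarray
    B: np.ndarray
    reml: float
    converged: bool
    n_evals: int
    best_restart: int
    theta_s: np.ndarray
    theta_n: np.ndarray


def _moment_start(design: StudyDesign, cov_kind: str):
    """Start Cn near the empirical trait covariance, Cs small."""
    C = design.n_contexts
    if design.layout == "complete":
        Ce = np.cov(design.Y.T) if C > 1 else np.atleast_2d(np.var(design.Y))
        Ce = np.atleast_2d(Ce)
        noise_diag = False
    else:
        Ce = np.diag(
            [
                max(np.var(design.y[design.contexts == a]), 1e-3)
                for a in range(C)
            ]
        )
        noise_diag = True
    Ce = 0.9 * Ce + 0.05 * np.mean(np.diag(Ce)) * np.eye(C)
    scale = float(np.sqrt(np.mean(np.diag(Ce))))
    k = n_params(cov_kind, C)
    theta_s = np.full(k, 0.3 * scale) if k else np.empty(0)
    if noise_diag:
        theta_n = 0.5 * np.log(np.maximum(np.diag(Ce), 1e-8))
    else:
        L = sla.cholesky(Ce, lower=True)
        theta_n = L[np.tril_indices(C)].copy()
        di = np.cumsum(np.arange(1, C + 1)) - 1  # positions of diagonal in tril order
        theta_n[di] = np.log(np.maximum(np.diag(L), 1e-8))
    return theta_s, theta_n


def fit(
    design: StudyDesign,
    region: RegionGenotypes,
    cov_kind: str = "full",
    restarts: int = 3,
    grad_tol: float = 1e-5,
    max_evals: int = 500,
    seed: int = 0,
    workspace=None,
    start: tuple | None = None,
) -> FittedModel:
    """Minimize the REML objective by L-BFGS from multiple starts.

    The first start is moment-based (empirical trait covariance); further
    restarts perturb it on a seeded stream.  The best optimum across
    restarts is returned with convergence diagnostics.
    """
    C = design.n_contexts
    cov = _as_cov(cov_kind, C)
    noise = _NoiseCov(C, diagonal=design.layout == "stratified")
    if workspace is None:
        workspace = (
            _CompleteWorkspace(design, region)
            if design.layout == "complete"
            else _StratifiedWorkspace(design, region)
        )
    use_grad = design.layout == "complete"
    k_s = cov.n_free
    rng = np.random.default_rng(seed)
    ts0, tn0 = start if start is not None else _moment_start(design, cov_kind)

    n_evals = 0

    def objective(theta):
        nonlocal n_evals
        n_evals += 1
        ts, tn = theta[:k_s], theta[k_s:]
        try:
            if use_grad:
                return reml_objective(
                    design, region, cov_kind, ts, tn, workspace=workspace, with_grad=True
                )
            return reml_objective(design, region, cov_kind, ts, tn, workspace=workspace)
        except FloatingPointError:
            if use_grad:
                return 1e12, np.zeros(theta.size)
            return 1e12

    best = None
    best_idx = -1
    for r in range(max(restarts, 1)):
        if r == 0:
            x0 = np.concatenate([ts0, tn0])
        else:
            x0 = np.concatenate([ts0, tn0]) + 0.3 * rng.standard_normal(k_s + tn0.size)
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            jac=use_grad if use_grad else None,
            options=dict(maxfun=max_evals, gtol=grad_tol, ftol=1e-10),
        )
        if best is None or res.fun < best.fun - 1e-12:
            best, best_idx = res, r
    ts, tn = best.x[:k_s], best.x[k_s:]
    Cs = cov.materialize(ts)
    Cn = noise.materialize(tn)
    B = _gls_fixed_effects(design, region, Cs, Cn)
    converged = bool(best.success) and np.isfinite(best.fun)
    return FittedModel(
        cov_kind=cov_kind,
        Cs=Cs,
        Cn=Cn,
        B=B,
        reml=-float(best.fun),
        converged=converged,
        n_evals=n_evals,
        best_restart=best_idx,
        theta_s=ts,
        theta_n=tn,
    )


def _gls_fixed_effects(design, region, Cs, Cn):
    """Profile the K x C fixed-effect matrix by GLS at the fitted covariance."""
    C = design.n_contexts
    K = design.F.shape[1]
    if K == 0:
        return np.zeros((0, C))
    N = design.n_individuals
    if design.layout == "complete":
        lam, U = region.eig()
        E = sla.cholesky(Cn, lower=True)
        Ei = sla.solve_triangular(E, np.eye(C), lower=True)
        d, Q = sla.eigh(Ei @ Cs @ Ei.T)
        d = np.maximum(d, 0.0)
        M = Ei.T @ Q
        Yt = (U.T @ design.Y) @ M
        Ft = U.T @ design.F
        s = np.outer(lam, d) + 1.0
        Bp = np.empty((K, C))
        for c in range(C):
            W = 1.0 / s[:, c]
            A = Ft.T @ (W[:, None] * Ft)
            Bp[:, c] = sla.solve(A, Ft.T @ (W * Yt[:, c]), assume_a="pos")
        return Bp @ np.linalg.inv(M)  # back to original context basis
    # stratified: build V^-1 products via Woodbury on the fly (N small in use)
    ctx = design.contexts
    S = region.n_variants
    dn = np.diag(Cn)[ctx]
    dcs, Qcs = sla.eigh(Cs)
    Ls = Qcs * np.sqrt(np.maximum(dcs, 0.0))
    Z = np.concatenate(
        [Ls[ctx, k, None] * region.G / np.sqrt(S) for k in range(C)], axis=1
    )
    Di = 1.0 / dn
    Aw = np.eye(Z.shape[1]) + Z.T @ (Di[:, None] * Z)
    cho = sla.cho_factor(Aw, lower=True)

    def vinv(x):
        dx = Di[:, None] * x if x.ndim > 1 else Di * x
        return dx - (Di[:, None] if x.ndim > 1 else Di) * (
            Z @ sla.cho_solve(cho, Z.T @ dx)
        )

    X = np.zeros((N, K * C))
    for a in range(C):
        m = ctx == a
        X[m, a * K : (a + 1) * K] = design.F[m]
    ViX = vinv(X)
    beta = sla.solve(X.T @ ViX, ViX.T @ design.y, assume_a="pos")
    return beta.reshape(C, K).T


def sample_phenotypes(fitted: FittedModel, design: StudyDesign, region: RegionGenotypes, seed: int):
    """Draw a phenotype replicate from the fitted model, in the design's layout.

    The set component is sampled through the genotypes (G z Ls^T / sqrt(S)),
    which realizes covariance Cs (x) Rs without factorizing an N x N matrix.
    """
    rng = np.random.default_rng(seed)
    C = design.n_contexts
    S = region.n_variants
    dcs, Qcs = sla.eigh(fitted.Cs)
    if dcs.min() < -1e-8 * max(1.0, abs(dcs).max()):
        raise ValueError("fitted Cs is not PSD")
    Ls = Qcs * np.sqrt(np.maximum(dcs, 0.0))
    if design.layout == "complete":
        N = design.n_individuals
        En = sla.cholesky(fitted.Cn, lower=True)
        Zg = rng.standard_normal((S, C))
        Us = region.G @ Zg @ Ls.T / np.sqrt(S)
        noise = rng.standard_normal((N, C)) @ En.T
        mean = design.F @ fitted.B if design.F.shape[1] else 0.0
        return mean + Us + noise
    ctx = design.contexts
    N = design.n_individuals
    u = np.zeros(N)
    for k in range(C):
        u += Ls[ctx, k] * (region.G @ rng.standard_normal(S)) / np.sqrt(S)
    sd = np.sqrt(np.diag(fitted.Cn))[ctx]
    noise = sd * rng.standard_normal(N)
    if design.F.shape[1]:
        mean = np.einsum("ij,ji->i", design.F, fitted.B[:, ctx])
    else:
        mean = 0.0
    return mean + u + noise


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------


class KroneckerSetLMM(BaseEstimator):
    """Kronecker-structured set-component LMM as an sklearn-style estimator.

    Parameters
    ----------
    cov_kind : str
        Structure of the set trait-context covariance: 'null', 'block',
        'rank1' or 'full'.
    restarts, grad_tol, max_evals : optimizer options.
    random_state : seed for the restart stream.

    After ``fit(G, Y, F=...)`` the fitted attributes are ``Cs_``, ``Cn_``,
    ``B_``, ``reml_``, ``converged_``, ``n_evals_``.
    """

    def __init__(self, cov_kind="full", restarts=3, grad_tol=1e-5, max_evals=500, random_state=0):
        self.cov_kind = cov_kind
        self.restarts = restarts
        self.grad_tol = grad_tol
        self.max_evals = max_evals
        self.random_state = random_state

    def fit(self, G, Y, F=None, contexts=None, n_contexts=None):
        """Fit from raw standardized genotypes G and phenotypes Y.

        Y two-dimensional -> complete design; one-dimensional with
        ``contexts`` -> stratified design.
        """
        G = np.asarray(G, dtype=float)
        region = RegionGenotypes(G)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 2:
            design = StudyDesign(layout="complete", Y=Y, F=F)
        else:
            design = StudyDesign(
                layout="stratified", y=Y, contexts=contexts, F=F, n_contexts=n_contexts
            )
        m = fit(
            design,
            region,
            cov_kind=self.cov_kind,
            restarts=self.restarts,
            grad_tol=self.grad_tol,
            max_evals=self.max_evals,
            seed=self.random_state,
        )
        self.Cs_ = m.Cs
        self.Cn_ = m.Cn
        self.B_ = m.B
        self.reml_ = m.reml
        self.converged_ = m.converged
        self.n_evals_ = m.n_evals
        self.model_ = m
        self.design_ = design
        self.region_ = region
        return self

    def sample(self, seed=0):
        """Draw one phenotype replicate from the fitted model."""
        return sample_phenotypes(self.model_, self.design_, self.region_, seed)
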