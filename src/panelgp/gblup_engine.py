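"""GBLUP: genomic relationship matrix, AI-REML and mixed-model equations.

Model
-----
``y = 1·mu + Z g + e`` with ``g ~ N(0, G·sigma_g2)`` and
``e ~ N(0, I·sigma_e2)``.  ``G`` is VanRaden's marker-based relationship
matrix ``W W' / (2 Σ p_k (1 - p_k))`` where ``W = M - 2P`` centers the 0/1/2
genotype matrix by twice the allele frequencies.

Variance components are estimated by average-information REML: Newton steps
with the AI matrix (Johnson & Thompson form), step-halving when the
restricted likelihood would decrease, and a fallback EM-REML step when an AI
update leaves the parameter space.  All per-iteration quantities are O(n)
after one eigendecomposition of the (training) G, since
``V = sigma_g2·G + sigma_e2·I`` is diagonal in the eigenbasis of ``G``.

Breeding values for all individuals (phenotyped or not) come from the joint
mixed-model equations; unphenotyped individuals simply have no record row in
``Z`` and are predicted through their relationships.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """VanRaden genomic relationship matrix with its sample ids."""

    matrix: np.ndarray
    samples: list[str]
    denominator: float  # 2 Σ p_k (1 - p_k)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    converged: bool
    n_iterations: int
    log_likelihood: float
    logl_history: list | None = None  # accepted restricted logL per iteration

    @property
    def heritability(self) -> float:
        total = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / total if total > 0 else np.nan


@dataclass
class MixedModelFit:
    """Joint MME solution: overall mean and GEBVs for every individual in G."""

    mu_hat: float
    g_hat: np.ndarray
    variance_components: VarianceComponents


def build_grm(dataset: GenotypeDataset) -> GRM:
    """G = WW'/(2 Σ p_k (1-p_k)) with mean-imputation of missing dosages.

    Allele frequencies are the dataset's own; monomorphic markers center to a
    zero column and contribute nothing to the denominator.
    """
    p = dataset.allele_frequencies()
    p = np.where(np.isnan(p), 0.0, p)
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero G-matrix denominator")
    w = dataset.dosages.astype(float)
    w = np.where(w == MISSING, 2.0 * p, w)
    w -= 2.0 * p
    g = (w @ w.T) / denom
    g = 0.5 * (g + g.T)
    return GRM(g, list(dataset.samples), denom)


# ---------------------------------------------------------------------------
# AI-REML in the eigenbasis of G


def _profile(theta, d, y_r, x_r):
    """Restricted logL and P-projections for variances theta in the eigenbasis."""
    sg2, se2 = theta
    w = sg2 * d + se2                      # eigenvalues of V
    wi = 1.0 / w
    xtvx = np.sum(x_r * wi * x_r)          # X'V⁻¹X (scalar, X = 1)
    xtvy = np.sum(x_r * wi * y_r)
    beta = xtvy / xtvx
    py = wi * (y_r - x_r * beta)           # P y
    ypy = float(np.sum(y_r * py))
    logl = -0.5 * (np.sum(np.log(w)) + np.log(xtvx) + ypy)
    return logl, py, wi, xtvx


def _apply_p(v, wi, x_r, xtvx):
    """P v = V⁻¹v - V⁻¹x (x'V⁻¹x)⁻¹ x'V⁻¹v in the eigenbasis."""
    wv = wi * v
    return wv - wi * x_r * (np.sum(x_r * wv) / xtvx)


def ai_reml(
    y: np.ndarray,
    grm: GRM,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Estimate (sigma_g2, sigma_e2) by AI-REML for y = 1·mu + g + e.

    Starts from an equal split of Var(y).  AI (Newton) updates are
    step-halved until the restricted likelihood does not decrease; an update
    that exits the parameter space is replaced by an EM-REML step.
    Components are floored at 1e-8 × Var(y).  Non-convergence after
    ``max_iter`` returns a flagged result rather than raising.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n != grm.n:
        raise ValueError(f"phenotype length {n} != GRM size {grm.n}")
    vary = float(np.var(y, ddof=1)) if n > 1 else 0.0
    if vary <= 0:
        floor = 1e-12
        return VarianceComponents(floor, floor, True, 0, 0.0)
    floor = 1e-8 * vary

    d, u = np.linalg.eigh(grm.matrix)
    d = np.maximum(d, 0.0)
    y_r = u.T @ y
    x_r = u.T @ np.ones(n)

    theta = np.array([vary / 2.0, vary / 2.0])
    logl, py, wi, xtvx = _profile(theta, d, y_r, x_r)
    history = [logl]
    n_iter = 0
    converged = False

    # scale for judging gradients: d logL / d theta is O(n / Var(y)) at the start
    grad_scale = n / vary

    for n_iter in range(1, max_iter + 1):
        dpy = d * py
        p_dpy = _apply_p(dpy, wi, x_r, xtvx)
        p_py = _apply_p(py, wi, x_r, xtvx)

        # gradients of the restricted logL w.r.t. (sigma_g2, sigma_e2)
        tr_pg = np.sum(d * wi) - np.sum(x_r * wi * d * wi * x_r) / xtvx
        tr_p = np.sum(wi) - np.sum(x_r * wi * wi * x_r) / xtvx
        grad = np.array([
            -0.5 * (tr_pg - float(py @ dpy)),
            -0.5 * (tr_p - float(py @ py)),
        ])

        # KKT check: each component is stationary, or floored with the
        # gradient pushing outward (boundary optimum)
        at_floor = theta <= 1.5 * floor
        kkt = (np.abs(grad) < 1e-6 * grad_scale) | (at_floor & (grad < 0))
        if kkt.all():
            converged = True
            break

        ai = 0.5 * np.array([
            [float(dpy @ p_dpy), float(dpy @ p_py)],
            [float(dpy @ p_py), float(py @ p_py)],
        ])

        try:
            step = np.linalg.solve(ai, grad)
        except np.linalg.LinAlgError:
            step = None

        new_theta = None
        if step is not None:
            # truncate a step that exits the parameter space at the boundary
            alpha = 1.0
            neg = step < 0
            if np.any(theta + step < floor) and neg.any():
                limits = (theta[neg] - floor) / -step[neg]
                alpha = min(1.0, 0.99 * float(limits.min()))
            if alpha > 1e-8:
                cand = theta + alpha * step
                # step-halving until the restricted likelihood does not drop
                for _ in range(20):
                    cand_logl, *_ = _profile(cand, d, y_r, x_r)
                    if cand_logl >= logl - 1e-12:
                        new_theta = cand
                        break
                    cand = theta + (cand - theta) / 2.0
        if new_theta is None:
            # EM-REML fallback: theta_i += 2 theta_i^2 grad_i / n, then floor
            em = theta + 2.0 * theta**2 * grad / n
            new_theta = np.maximum(em, floor)

        new_logl, py, wi, xtvx = _profile(new_theta, d, y_r, x_r)
        rel_change = np.max(np.abs(new_theta - theta) / (np.abs(theta) + floor))
        dl = abs(new_logl - logl)
        theta, logl = new_theta, new_logl
        history.append(logl)
        if rel_change < tol and dl < tol:
            converged = True
            break

    if not converged:
        # final KKT check at the last iterate
        dpy = d * py
        tr_pg = np.sum(d * wi) - np.sum(x_r * wi * d * wi * x_r) / xtvx
        tr_p = np.sum(wi) - np.sum(x_r * wi * wi * x_r) / xtvx
        grad = np.array([-0.5 * (tr_pg - float(py @ dpy)),
                         -0.5 * (tr_p - float(py @ py))])
        at_floor = theta <= 1.5 * floor
        kkt = (np.abs(grad) < 1e-4 * grad_scale) | (at_floor & (grad < 0))
        converged = bool(kkt.all())

    return VarianceComponents(float(theta[0]), float(theta[1]), converged,
                              n_iter, float(logl), logl_history=history)


# ---------------------------------------------------------------------------
# Mixed-model equations


def solve_mme(
    y_train: np.ndarray,
    grm_all: GRM,
    vc: VarianceComponents,
    train_indices: np.ndarray | None = None,
) -> MixedModelFit:
    """Solve the joint MME for mu and the GEBVs of all individuals in G.

    ``train_indices`` maps the records in ``y_train`` onto rows of ``G``
    (default: the first len(y_train) individuals).  The joint MME

        [ n_t/se2      z'/se2          ] [mu]   [ Σy/se2    ]
        [ z/se2   Z'Z/se2 + (G·sg2)⁻¹  ] [g ] = [ Z'y/se2   ]

    is solved in its G-premultiplied form (random-effect block scaled by
    sg2·G), which has the same unique solution but needs no G inverse, so a
    VanRaden G — exactly singular because its centered columns put the
    1-vector in the null space — needs no ridge.  A declared 1e-8 diagonal
    ridge remains as a logged fallback should the premultiplied system
    itself be singular.
    """
    y_train = np.asarray(y_train, dtype=float)
    n_all = grm_all.n
    if train_indices is None:
        train_indices = np.arange(y_train.size)
    train_indices = np.asarray(train_indices, dtype=np.intp)
    if train_indices.size != y_train.size:
        raise ValueError("train_indices length must match y_train")

    sg2, se2 = max(vc.sigma_g2, 1e-12), max(vc.sigma_e2, 1e-12)
    g_cov = grm_all.matrix * sg2

    z_ind = np.zeros(n_all)
    z_ind[train_indices] = 1.0
    zty = np.zeros(n_all)
    zty[train_indices] = y_train
    n_t = y_train.size

    # rows 1..n: sg2·G·Z'Z·g + se2·g + sg2·G·z·mu = sg2·G·Z'y
    lhs = np.empty((n_all + 1, n_all + 1))
    lhs[0, 0] = n_t
    lhs[0, 1:] = z_ind
    lhs[1:, 0] = g_cov @ z_ind
    lhs[1:, 1:] = g_cov * z_ind[None, :] + se2 * np.eye(n_all)
    rhs = np.concatenate([[y_train.sum()], g_cov @ zty])

    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        logger.info("singular mixed-model system: adding 1e-8 ridge")
        sol = np.linalg.solve(lhs + 1e-8 * np.eye(n_all + 1), rhs)
    return MixedModelFit(float(sol[0]), sol[1:], vc)


def blup_oracle(
    y_train: np.ndarray,
    grm_all: GRM,
    vc: VarianceComponents,
    train_indices: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Direct V⁻¹-based GLS/BLUP solution (reference implementation).

    mu = (1'V⁻¹1)⁻¹ 1'V⁻¹ y with V = G_tt·sg2 + I·se2 over training records;
    ĝ = sg2 · G[:, train] V⁻¹ (y - mu).  Used as an independent cross-check
    of :func:`solve_mme`; O(n_train³) without structure exploitation.
    """
    sg2, se2 = vc.sigma_g2, vc.sigma_e2
    g_tt = grm_all.matrix[np.ix_(train_indices, train_indices)]
    v = sg2 * g_tt + se2 * np.eye(train_indices.size)
    vi = np.linalg.inv(v)
    ones = np.ones(train_indices.size)
    mu = float(ones @ vi @ y_train) / float(ones @ vi @ ones)
    g_hat = sg2 * grm_all.matrix[:, train_indices] @ (vi @ (y_train - mu))
    return mu, g_hat
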