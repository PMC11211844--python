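"""Joint maximum-likelihood fitting of branch lengths and model parameters.

The joint likelihood is the product of the spatial (symmetric-displacement)
likelihood and the sequence (editing-chain) likelihood on a shared, fixed
tree topology.  The optimization co-estimates node times (equivalently
branch lengths), the diffusion rate sigma, the division angles, the root
location, and the sequence rates (lambda, nu, phi), subject to the
common-sampling-time constraint: every leaf sits exactly at ``tau_end``.
The displacement magnitude ``r`` is a fixed input (co-estimating it with
sigma is known to be unstable); a sweep helper fits a user-supplied grid.

Constraint handling: node times are reparameterized root-down as
``t_v = t_parent + (tau_end - t_parent) * sigmoid(raw_v)`` with leaves
pinned at ``tau_end``, so the constraint holds exactly by construction and
an unconstrained quasi-Newton optimizer (L-BFGS-B with finite-difference
gradients) can be used.  Multiple restarts jitter the starting point; the
best restart is returned and the procedure is deterministic given the seed.

Reported diffusion rate: maximizing over the division angles deflates the
ML variance estimate (each fitted angle absorbs about one degree of freedom
of the 2N-dimensional location data), so the headline ``sigma`` applies a
REML-style correction ``sigma_ml * sqrt(2N / (2N - p))`` with ``p`` the
number of fitted mean-structure parameters (root coordinates plus angles).
The uncorrected ML value is kept as ``sigma_mle``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import trees
from ._flat import (
    FlatTree,
    deltas_from_times,
    pmm_loglik_kernel,
    sd_loglik_kernel,
    sd_prune_kernel,
    times_from_raw,
)
from .sequence_pmm import (
    CharacterMatrix,
    PMMParams,
    _encode_column,
    _stack_sites,
    sequence_loglik,
)
from .spatial_sd import (
    BRANCH_FLOOR_REL,
    LeafLocations,
    SDParams,
    sd_loglik_dense,
    sd_loglik_fast,
    sd_loglik_marginal_reml,
    sd_loglik_marginal_reml_dense,
)

__all__ = [
    "ModelConfig",
    "FitResult",
    "joint_loglik",
    "node_times_to_raw",
    "raw_to_node_times",
    "fit",
    "r_sweep",
]

MODALITIES = ("S", "L", "S+L")


@dataclass
class ModelConfig:
    """Configuration of one fit.

    modality : "S" (sequence only), "L" (location only) or "S+L" (joint)
    r        : fixed displacement magnitude (ignored in modality "S")
    tau_end  : experiment duration; every leaf is pinned at this time
    restarts : number of optimizer restarts (>= 1)
    seed     : base seed; restart i uses seed + i
    tol      : relative log-likelihood change declaring convergence
    max_iter : L-BFGS-B iteration cap per restart
    fixed    : parameters held at given values, e.g. {"x0": 0.0, "nu": 0.0}
               (allowed keys: sigma, x0, y0, lam, nu, phi)
    angle_mode : "marginal" (default) integrates the division
               displacements out as latent Gaussian vectors of per-axis
               variance r^2/2, estimating no per-division parameter;
               "conditional" maximizes over one angle per division (the
               literal joint-ML objective) and applies a REML-style
               degrees-of-freedom correction to the reported sigma.
    """

    modality: str = "S+L"
    r: float = 0.0
    tau_end: float = 1.0
    restarts: int = 10
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 1000
    fixed: dict = field(default_factory=dict)
    angle_mode: str = "marginal"

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.angle_mode not in ("marginal", "conditional"):
            raise ValueError("angle_mode must be 'marginal' or 'conditional'")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not self.tau_end > 0:
            raise ValueError("tau_end must be > 0")
        if self.r < 0:
            raise ValueError("r must be >= 0")
        bad = set(self.fixed) - {"sigma", "x0", "y0", "lam", "nu", "phi"}
        if bad:
            raise ValueError(f"cannot fix parameters {sorted(bad)}")


@dataclass
class FitResult:
    """Outcome of :func:`fit`: fitted tree, parameter estimates,
    per-component log-likelihoods and per-restart diagnostics."""

    tree: trees.LineageTree
    modality: str
    r: float
    tau_end: float
    angle_mode: str
    sigma: Optional[float]        # dof-corrected (reported) diffusion rate
    sigma_mle: Optional[float]
    theta: dict[int, float]
    x0: Optional[float]
    y0: Optional[float]
    lam: Optional[float]
    nu: Optional[float]
    phi: Optional[float]
    loglik: float
    loglik_spatial: Optional[float]
    loglik_sequence: Optional[float]
    converged: bool
    restarts: list[dict]
    n_parameters: int
    dense_check: Optional[float] = None   # |fast - dense| at the optimum

    def sd_params(self) -> SDParams:
        if self.sigma_mle is None:
            raise ValueError("no spatial parameters in this fit")
        return SDParams(sigma=self.sigma_mle, r=self.r, theta=dict(self.theta),
                        x0=self.x0, y0=self.y0)

    def pmm_params(self) -> PMMParams:
        if self.lam is None:
            raise ValueError("no sequence parameters in this fit")
        return PMMParams(lam=self.lam, nu=self.nu, phi=self.phi)

    def to_dict(self) -> dict:
        d = {
            "modality": self.modality,
            "r": self.r,
            "tau_end": self.tau_end,
            "angle_mode": self.angle_mode,
            "sigma": self.sigma,
            "sigma_mle": self.sigma_mle,
            "theta": {str(k): v for k, v in self.theta.items()},
            "x0": self.x0,
            "y0": self.y0,
            "lambda": self.lam,
            "nu": self.nu,
            "phi": self.phi,
            "loglik": self.loglik,
            "loglik_spatial": self.loglik_spatial,
            "loglik_sequence": self.loglik_sequence,
            "converged": self.converged,
            "n_parameters": self.n_parameters,
            "dense_check": self.dense_check,
            "restarts": self.restarts,
            "newick": trees.write_newick(self.tree),
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# joint likelihood
# ---------------------------------------------------------------------------

def joint_loglik(
    tree: trees.LineageTree,
    matrix: Optional[CharacterMatrix],
    locations: Optional[LeafLocations],
    sd_params: Optional[SDParams],
    pmm_params: Optional[PMMParams],
    modality: str = "S+L",
    angle_mode: str = "conditional",
) -> float:
    """Sum of the modality's component log-likelihoods.

    "S+L" adds the spatial and sequence log-likelihoods (the two data
    modalities are independent given the tree); "S" and "L" use one
    component and ignore the other inputs entirely.  ``angle_mode``
    selects the spatial likelihood: "conditional" on the division angles
    in ``sd_params.theta`` (the default), or "marginal" with the angles
    integrated out (the form :func:`fit` optimizes by default).
    """
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}")
    ll = 0.0
    if modality in ("L", "S+L"):
        if locations is None or sd_params is None:
            raise ValueError("modality requires locations and sd_params")
        if angle_mode == "conditional":
            ll += sd_loglik_fast(tree, locations, sd_params)
        elif angle_mode == "marginal":
            ll += sd_loglik_marginal_reml(
                tree, locations, sd_params.sigma, sd_params.r)[0]
        else:
            raise ValueError("angle_mode must be 'marginal' or "
                             "'conditional'")
    if modality in ("S", "S+L"):
        if matrix is None or pmm_params is None:
            raise ValueError("modality requires a character matrix and "
                             "pmm_params")
        ll += sequence_loglik(tree, matrix, pmm_params)
    return ll


# ---------------------------------------------------------------------------
# node-time reparameterization (public API)
# ---------------------------------------------------------------------------

def raw_to_node_times(
    tree: trees.LineageTree, raw: np.ndarray, tau_end: float
) -> trees.NodeTimes:
    """Map an unconstrained vector (one entry per internal non-root node,
    preorder) to node times satisfying the leaf constraint exactly.
    The zero vector places each internal node at the midpoint of its
    feasible interval."""
    flat = FlatTree(tree)
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (flat.n_free,):
        raise ValueError(f"raw must have length {flat.n_free}")
    t = times_from_raw(flat.preorder, flat.parent, flat.is_leaf,
                       flat.free_idx, raw, tau_end)
    return trees.NodeTimes(time={int(v): float(t[v]) for v in flat.preorder},
                           tau_end=tau_end)


def node_times_to_raw(
    tree: trees.LineageTree, times: trees.NodeTimes
) -> np.ndarray:
    """Inverse of :func:`raw_to_node_times` (round trip to ~1e-12)."""
    flat = FlatTree(tree)
    tau = times.tau_end
    raw = np.empty(flat.n_free)
    for i, v in enumerate(flat.free_nodes):
        tp = times.time[int(flat.parent[v])]
        tv = times.time[int(v)]
        frac = (tv - tp) / (tau - tp)
        if not 0.0 < frac < 1.0:
            raise ValueError(f"node {v} time outside its feasible interval")
        raw[i] = logit(frac)
    return raw


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class _Problem:
    """Packs/unpacks the parameter vector and evaluates -loglik fast."""

    RAW_BOUND = 16.0

    def __init__(self, tree, matrix, locations, config):
        self.config = config
        self.flat = FlatTree(tree)
        self.tau = config.tau_end
        self.floor = BRANCH_FLOOR_REL * self.tau
        self.use_L = config.modality in ("L", "S+L")
        self.use_S = config.modality in ("S", "S+L")
        fixed = config.fixed

        if self.use_L:
            loc = locations.reorder(self.flat.leaf_names)
            self.xs, self.ys = loc.x, loc.y
        if self.use_S:
            mat = matrix.reorder(self.flat.leaf_names)
            self.obs = np.column_stack([
                _encode_column(mat.data[:, k], mat.alphabets[k], False)
                for k in range(mat.n_sites)
            ])
            self.pi, self.m_k = _stack_sites(mat.alphabets)
            self._site_scratch = np.empty(mat.n_sites)

        # vector layout: raw times | spatial scalars | theta | seq scalars
        names: list[tuple[str, int]] = [("raw", self.flat.n_free)]
        self.free_scalars: list[str] = []
        self.conditional = (config.angle_mode == "conditional")
        if self.use_L:
            # marginal mode is a restricted likelihood: the root position
            # integrates out and is never a free parameter
            scalar_names = (("log_sigma", "x0", "y0") if self.conditional
                            else ("log_sigma",))
            for nm in scalar_names:
                key = nm.replace("log_", "")
                if key not in fixed:
                    self.free_scalars.append(nm)
            self.n_theta = (self.flat.n_bif
                            if (config.r > 0 and self.conditional) else 0)
            self.rho2 = (0.0 if self.conditional
                         else 0.5 * config.r ** 2)
        else:
            self.n_theta = 0
            self.rho2 = 0.0
        if self.use_S:
            for nm in ("log_lam", "log_nu", "logit_phi"):
                key = {"log_lam": "lam", "log_nu": "nu",
                       "logit_phi": "phi"}[nm]
                if key not in fixed:
                    self.free_scalars.append(nm)
        self.n_free_scalars = len(self.free_scalars)
        self.dim = self.flat.n_free + self.n_free_scalars + self.n_theta
        self.i_scalar = {nm: self.flat.n_free + i
                         for i, nm in enumerate(self.free_scalars)}
        self.sl_theta = slice(self.flat.n_free + self.n_free_scalars,
                              self.dim)

    def bounds(self):
        b = [(-self.RAW_BOUND, self.RAW_BOUND)] * self.flat.n_free
        lim = {"log_sigma": (-12.0, 12.0), "x0": (None, None),
               "y0": (None, None), "log_lam": (-18.0, 6.0),
               "log_nu": (-18.0, 6.0), "logit_phi": (-18.0, 10.0)}
        b += [lim[nm] for nm in self.free_scalars]
        b += [(None, None)] * self.n_theta
        return b

    def _scalar(self, vec, name, transform, fixed_key):
        if name in self.i_scalar:
            return transform(vec[self.i_scalar[name]])
        return self.config.fixed[fixed_key]

    def unpack(self, vec):
        out = {}
        if self.use_L:
            out["sigma"] = self._scalar(vec, "log_sigma", np.exp, "sigma")
            if self.conditional:
                out["x0"] = self._scalar(vec, "x0", float, "x0")
                out["y0"] = self._scalar(vec, "y0", float, "y0")
            out["theta"] = (np.mod(vec[self.sl_theta], 2 * np.pi)
                            if self.n_theta else np.zeros(self.flat.n_bif))
        if self.use_S:
            out["lam"] = self._scalar(vec, "log_lam", np.exp, "lam")
            out["nu"] = self._scalar(vec, "log_nu", np.exp, "nu")
            out["phi"] = self._scalar(vec, "logit_phi", expit, "phi")
        return out

    def deltas(self, vec):
        t = times_from_raw(self.flat.preorder, self.flat.parent,
                           self.flat.is_leaf, self.flat.free_idx,
                           vec[: self.flat.n_free], self.tau)
        return deltas_from_times(self.flat.parent, t), t

    def components(self, vec):
        """(spatial, sequence) log-likelihood at the packed point."""
        fl = self.flat
        delta, _ = self.deltas(vec)
        ll_L = ll_S = None
        if self.use_L:
            sigma = self._scalar(vec, "log_sigma", np.exp, "sigma")
            if self.conditional:
                x0 = self._scalar(vec, "x0", float, "x0")
                y0 = self._scalar(vec, "y0", float, "y0")
                if self.n_theta:
                    dx, dy = fl.displacement_shifts(
                        self.config.r, vec[self.sl_theta])
                else:
                    dx = dy = np.zeros(fl.n)
                ll_L = sd_loglik_kernel(
                    fl.postorder, fl.parent, fl.child1, fl.child2,
                    fl.is_leaf, fl.leaf_row, delta, dx, dy,
                    self.xs, self.ys, x0, y0, sigma ** 2, self.floor,
                    self.rho2,
                )
            else:
                zero = np.zeros(fl.n)
                ll_L, _, _, _ = sd_prune_kernel(
                    fl.postorder, fl.parent, fl.child1, fl.child2,
                    fl.is_leaf, fl.leaf_row, delta, zero, zero,
                    self.xs, self.ys, sigma ** 2, self.floor, self.rho2,
                )
        if self.use_S:
            lam = self._scalar(vec, "log_lam", np.exp, "lam")
            nu = self._scalar(vec, "log_nu", np.exp, "nu")
            phi = self._scalar(vec, "logit_phi", expit, "phi")
            ll_S = pmm_loglik_kernel(
                fl.postorder, fl.child1, fl.child2, fl.is_leaf, fl.leaf_row,
                delta, self.obs, self.pi, self.m_k, lam, nu, phi,
                self._site_scratch,
            )
        return ll_L, ll_S

    def root_gls(self, vec):
        """GLS estimate of the root position at the packed point."""
        fl = self.flat
        delta, _ = self.deltas(vec)
        sigma = self._scalar(vec, "log_sigma", np.exp, "sigma")
        zero = np.zeros(fl.n)
        _, mxr, myr, _ = sd_prune_kernel(
            fl.postorder, fl.parent, fl.child1, fl.child2, fl.is_leaf,
            fl.leaf_row, delta, zero, zero, self.xs, self.ys,
            sigma ** 2, self.floor, self.rho2,
        )
        return float(mxr), float(myr)

    def negloglik(self, vec):
        ll_L, ll_S = self.components(vec)
        ll = (ll_L or 0.0) + (ll_S or 0.0)
        if not np.isfinite(ll):
            return 1e12
        return -ll


def _initial_times_raw(problem: _Problem, tree: trees.LineageTree):
    """Starting raw-time vector: input branch lengths scaled to tau_end if
    available, else the midpoint cascade (zero vector)."""
    flat = problem.flat
    if flat.n_free == 0:
        return np.zeros(0)
    if not tree.has_lengths():
        return np.zeros(flat.n_free)
    delta = flat.branch_lengths()
    depth = np.zeros(flat.n)
    for v in flat.preorder:
        if flat.parent[v] >= 0:
            depth[v] = depth[flat.parent[v]] + delta[v]
    dmax = depth[flat.is_leaf].max()
    if dmax <= 0:
        return np.zeros(flat.n_free)
    t = depth * (problem.tau / dmax)
    raw = np.zeros(flat.n_free)
    for i, v in enumerate(flat.free_nodes):
        tp = t[flat.parent[v]]
        frac = np.clip((t[v] - tp) / max(problem.tau - tp, 1e-12),
                       1e-6, 1 - 1e-6)
        raw[i] = np.clip(logit(frac), -problem.RAW_BOUND, problem.RAW_BOUND)
    return raw


def _moment_theta(problem: _Problem) -> np.ndarray:
    """Per-division angle start: direction between the two daughter
    subtrees' leaf centroids (falls back to 0 for degenerate geometry)."""
    fl = problem.flat
    theta = np.zeros(fl.n_bif)
    # leaf sets per node by postorder accumulation
    sums = np.zeros((fl.n, 3))  # sum x, sum y, count
    for u in fl.postorder:
        if fl.is_leaf[u]:
            row = fl.leaf_row[u]
            sums[u] = (problem.xs[row], problem.ys[row], 1.0)
        else:
            for c in (fl.child1[u], fl.child2[u]):
                if c >= 0:
                    sums[u] += sums[c]
    for i, u in enumerate(fl.bif_nodes):
        a, b = fl.child1[u], fl.child2[u]
        ax, ay = sums[a][0] / sums[a][2], sums[a][1] / sums[a][2]
        bx, by = sums[b][0] / sums[b][2], sums[b][1] / sums[b][2]
        if (ax - bx) ** 2 + (ay - by) ** 2 > 0:
            theta[i] = np.arctan2(ay - by, ax - bx)
    return theta


def _initial_vector(problem: _Problem, tree, matrix, locations, rng,
                    restart: int) -> np.ndarray:
    cfg = problem.config
    vec = np.zeros(problem.dim)
    raw0 = _initial_times_raw(problem, tree)
    if restart > 0:
        raw0 = np.clip(raw0 + rng.normal(0, 1.0, raw0.shape),
                       -problem.RAW_BOUND, problem.RAW_BOUND)
    vec[: problem.flat.n_free] = raw0
    if problem.use_L:
        xs, ys = problem.xs, problem.ys
        sig0 = float(np.sqrt(
            np.mean((xs - xs.mean()) ** 2 + (ys - ys.mean()) ** 2)
            / cfg.tau_end))
        sig0 = max(sig0, 1e-6)
        if restart > 0:
            sig0 *= np.exp(rng.normal(0, 0.3))
        if "log_sigma" in problem.i_scalar:
            vec[problem.i_scalar["log_sigma"]] = np.log(sig0)
        if "x0" in problem.i_scalar:
            vec[problem.i_scalar["x0"]] = xs.mean() + \
                (rng.normal(0, 0.3 * sig0 * np.sqrt(cfg.tau_end))
                 if restart > 0 else 0.0)
        if "y0" in problem.i_scalar:
            vec[problem.i_scalar["y0"]] = ys.mean() + \
                (rng.normal(0, 0.3 * sig0 * np.sqrt(cfg.tau_end))
                 if restart > 0 else 0.0)
        if problem.n_theta:
            if restart == 0:
                vec[problem.sl_theta] = _moment_theta(problem)
            else:
                vec[problem.sl_theta] = rng.uniform(
                    0, 2 * np.pi, problem.n_theta)
    if problem.use_S:
        obs = problem.obs
        seen = obs != trees.MISSING
        frac0 = ((obs == 0) & seen).sum() / max(seen.sum(), 1)
        lam0 = -np.log(max(frac0, 1e-6)) / cfg.tau_end
        lam0 = float(np.clip(lam0, 1e-8, 100.0 / cfg.tau_end))
        if restart > 0:
            lam0 *= np.exp(rng.normal(0, 0.5))
        if "log_lam" in problem.i_scalar:
            vec[problem.i_scalar["log_lam"]] = np.log(lam0)
        if "log_nu" in problem.i_scalar:
            nu0 = 0.01 * np.exp(rng.normal(0, 0.5)) if restart > 0 else 0.01
            vec[problem.i_scalar["log_nu"]] = np.log(nu0)
        if "logit_phi" in problem.i_scalar:
            phi0 = 0.01 * np.exp(rng.normal(0, 0.5)) if restart > 0 else 0.01
            vec[problem.i_scalar["logit_phi"]] = logit(min(phi0, 0.5))
    return vec


def _posthoc_theta(problem: _Problem, fitted, vec, config,
                   x0: float, y0: float) -> dict[int, float]:
    """Division angles reported after a marginal-mode fit: the conditional
    ML angles given the fitted times, sigma, and root location."""
    fl = problem.flat
    if fl.n_bif == 0 or config.r == 0.0:
        return {}
    delta, _ = problem.deltas(vec)
    sigma = problem._scalar(vec, "log_sigma", np.exp, "sigma")

    def neg(theta):
        dx, dy = fl.displacement_shifts(config.r, theta)
        return -sd_loglik_kernel(
            fl.postorder, fl.parent, fl.child1, fl.child2, fl.is_leaf,
            fl.leaf_row, delta, dx, dy, problem.xs, problem.ys,
            x0, y0, sigma ** 2, problem.floor, 0.0)

    res = minimize(neg, _moment_theta(problem), method="L-BFGS-B",
                   options={"maxiter": 300})
    theta = np.mod(res.x, 2 * np.pi)
    return {int(u): float(th) for u, th in zip(fl.bif_nodes, theta)}


def fit(
    tree: trees.LineageTree,
    matrix: Optional[CharacterMatrix],
    locations: Optional[LeafLocations],
    config: ModelConfig,
) -> FitResult:
    """Constrained joint ML fit on a fixed topology.

    Returns the best of ``config.restarts`` local optimizations.  The
    fitted tree satisfies the leaf-time constraint exactly; the returned
    log-likelihood is never worse than any restart's starting value.  If no
    restart converges the best point is still returned with
    ``converged=False``.
    """
    tree.validate()
    if config.modality in ("L", "S+L") and locations is None:
        raise ValueError(f"modality {config.modality} requires locations")
    if config.modality in ("S", "S+L") and matrix is None:
        raise ValueError(f"modality {config.modality} requires a character "
                         "matrix")
    problem = _Problem(tree, matrix, locations, config)
    best = None
    trace = []
    for i in range(config.restarts):
        rng = np.random.default_rng(config.seed + i)
        v0 = _initial_vector(problem, tree, matrix, locations, rng, i)
        f0 = problem.negloglik(v0)
        res = minimize(
            problem.negloglik, v0, method="L-BFGS-B",
            bounds=problem.bounds(),
            options={"maxiter": config.max_iter, "maxfun": 10 ** 6,
                     "ftol": config.tol * 1e-3, "eps": 1e-7},
        )
        fbest, vbest = (res.fun, res.x) if res.fun <= f0 else (f0, v0)
        rel_change = abs(res.fun - f0) / max(abs(f0), 1.0)
        entry = {
            "seed": config.seed + i,
            "start_loglik": -f0,
            "final_loglik": -fbest,
            "n_iter": int(res.nit),
            "converged": bool(res.success) or rel_change < config.tol,
        }
        trace.append(entry)
        if best is None or fbest < best[0]:
            best = (fbest, vbest, entry["converged"])

    fneg, vec, conv = best
    pars = problem.unpack(vec)
    delta, t = problem.deltas(vec)
    fitted = tree.copy()
    for v in fitted.preorder():
        if v != fitted.root:
            fitted.branch_length[v] = float(delta[v])

    ll_L, ll_S = problem.components(vec)
    N = len(problem.flat.leaf_names)
    theta_map, sigma, sigma_mle = {}, None, None
    x0 = y0 = lam = nu = phi = None
    dense_check = None
    if problem.use_L:
        sigma_mle = float(pars["sigma"])
        if problem.conditional:
            x0, y0 = float(pars["x0"]), float(pars["y0"])
            theta_map = {int(u): float(th) for u, th in
                         zip(problem.flat.bif_nodes, pars["theta"])}
            # ML variance estimates are deflated by the fitted
            # mean-structure parameters (root coordinates and one angle
            # per division); report the dof-corrected rate
            p_mean = (2 if ("x0" in problem.i_scalar or
                            "y0" in problem.i_scalar) else 0) \
                + problem.n_theta
            sigma = (sigma_mle * float(np.sqrt(2 * N / (2 * N - p_mean)))
                     if p_mean < 2 * N else sigma_mle)
            sd_at_opt = SDParams(sigma=sigma_mle, r=config.r,
                                 theta=theta_map, x0=x0, y0=y0)
            dense_check = abs(
                sd_loglik_dense(tree=fitted, locations=locations,
                                params=sd_at_opt, floor=problem.floor)
                - ll_L)
        else:
            sigma = sigma_mle  # no per-division parameter was fitted
            x0, y0 = problem.root_gls(vec)
            theta_map = _posthoc_theta(problem, fitted, vec, config, x0, y0)
            dense_check = abs(
                sd_loglik_marginal_reml_dense(
                    fitted, locations, sigma_mle, config.r,
                    floor=problem.floor)
                - ll_L)
    if problem.use_S:
        lam, nu, phi = (float(pars["lam"]), float(pars["nu"]),
                        float(pars["phi"]))

    return FitResult(
        tree=fitted, modality=config.modality, r=config.r,
        tau_end=config.tau_end, angle_mode=config.angle_mode,
        sigma=sigma, sigma_mle=sigma_mle, theta=theta_map,
        x0=x0, y0=y0, lam=lam, nu=nu, phi=phi,
        loglik=float(-fneg),
        loglik_spatial=None if ll_L is None else float(ll_L),
        loglik_sequence=None if ll_S is None else float(ll_S),
        converged=conv, restarts=trace, n_parameters=problem.dim,
        dense_check=dense_check,
    )


def r_sweep(
    tree: trees.LineageTree,
    matrix: Optional[CharacterMatrix],
    locations: Optional[LeafLocations],
    config: ModelConfig,
    r_grid,
) -> dict[float, FitResult]:
    """Fit once per value of the displacement magnitude ``r``."""
    out = {}
    for r in r_grid:
        cfg = ModelConfig(**{**asdict(config), "r": float(r)})
        out[float(r)] = fit(tree, matrix, locations, cfg)
    return out
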