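"""Ancestral thermal-tolerance inference under directional Brownian motion.

Thermal tolerance of each extant taxon is summarized by two ordered
continuous characters: the mean annual temperature of its coldest known
locality (T_cold) and of its warmest known locality (T_warm).  The pair is
modelled as correlated Brownian motion on the phylogram with Pagel's tree
transforms:

* ``kappa`` raises each branch length to a power (speciational vs gradual
  change),
* ``delta`` raises node depths — entries of the phylogenetic covariance
  matrix — to a power (early vs late rate change),
* ``lambda`` scales the off-diagonal (shared) covariance, measuring
  phylogenetic signal.

Two mean structures are compared: model A, a trendless random walk in which
tips have expectation ``alpha``; and model B, a directional random walk whose
expectation drifts with root-to-tip path length, ``alpha + beta * depth``.
Model B is only identifiable when root-to-tip path lengths vary, hence a
phylogram (not an ultrametric chronogram) is the intended input.

Inference is Bayesian: Metropolis–Hastings over (alpha, beta, Sigma, lambda
[, delta, kappa]) with flat priors on bounded supports; ancestral states at
interior nodes are drawn per retained posterior sample from the exact
conditional normal given the tips.  ML fits of the same likelihood support a
likelihood-ratio comparison of models A and B, and stepping-stone estimates
of the marginal likelihood give a Bayes factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.stats import chi2

from .trees import Phylogeny, TaxonTable, join_table, mrca

__all__ = [
    "BMModel",
    "MCMCConfig",
    "AncestralTolerance",
    "ThermalModel",
    "ThermalMLFit",
    "ThermalResults",
    "phylo_vcv",
    "transform_vcv",
    "compare_models",
]


@dataclass
class BMModel:
    """Two-trait Brownian parameters with Pagel transforms and optional trend."""

    model: str = "A"  # "A" random walk | "B" directional
    alpha: Tuple[float, float] = (0.0, 0.0)  # root states (cold, warm), degC
    beta: Tuple[float, float] = (0.0, 0.0)  # trend per unit path length
    sigma: np.ndarray = field(default_factory=lambda: np.eye(2))  # 2x2 rate matrix
    lam: float = 1.0
    delta: float = 1.0
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("A", "B"):
            raise ValueError("model must be 'A' or 'B'")
        self.sigma = np.asarray(self.sigma, dtype=float)
        ev = np.linalg.eigvalsh(self.sigma)
        if ev.min() < -1e-10:
            raise ValueError("Sigma must be positive semi-definite")
        if self.model == "A" and any(b != 0 for b in self.beta):
            raise ValueError("model A requires beta == 0")
        _check_transforms(self.lam, self.delta, self.kappa)


def _check_transforms(lam: float, delta: float, kappa: float) -> None:
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length and proposal configuration.

    The ``full`` preset mirrors the published run length for this kind of
    analysis (5e6 iterations, burn-in 5000, sample period 100); ``desk`` is
    the scaled-down default for interactive use and testing.
    """

    iterations: int = 200_000
    burn_in: int = 5_000
    sample_period: int = 100
    seed: int = 0
    scale_alpha: float = 2.0
    scale_beta: float = 20.0
    scale_logsig: float = 0.3
    scale_rho: float = 0.15
    scale_lam: float = 0.06
    scale_shape: float = 0.15  # delta / kappa, when estimated

    def __post_init__(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if self.sample_period < 1:
            raise ValueError("sample_period must be >= 1")

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "MCMCConfig":
        if name == "full":
            return cls(iterations=5_000_000, burn_in=5_000, sample_period=100,
                       seed=seed)
        if name == "desk":
            return cls(seed=seed)
        if name == "smoke":  # very short chain for integration checks
            return cls(iterations=20_000, burn_in=2_000, sample_period=50,
                       seed=seed)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class AncestralTolerance:
    """Posterior summary of (T_cold, T_warm) at one interior node."""

    node: int
    mean_cold: float
    mean_warm: float
    ci_cold: Tuple[float, float]
    ci_warm: Tuple[float, float]
    samples: Optional[np.ndarray] = None  # draws x 2
    ordering_violated: bool = False


# ---------------------------------------------------------------------------
# covariance machinery
# ---------------------------------------------------------------------------

def phylo_vcv(tree: Phylogeny) -> Tuple[np.ndarray, List[str]]:
    """Brownian tip covariance: V[i,j] = root-to-mrca(i,j) path length.

    Returns (V, tip labels in post-order)."""
    depths = tree.depths()
    tips = list(tree.tips)
    n = len(tips)
    below = tree.node_tips()
    tip_pos = {t: i for i, t in enumerate(tips)}
    V = np.zeros((n, n))
    # every node contributes its branch length to all tip pairs below it
    for node in tree.postorder():
        if tree.parent[node] < 0:
            continue
        idx = [tip_pos[t] for t in below[node]]
        V[np.ix_(idx, idx)] += tree.branch_length[node]
    return V, [tree.labels[t] for t in tips]


def _kappa_tree(tree: Phylogeny, kappa: float) -> Phylogeny:
    if kappa == 1.0:
        return tree
    b = tree.branch_length
    newb = np.where(b > 0, np.power(b, kappa, where=b > 0, out=np.zeros_like(b)), 0.0)
    return Phylogeny(tree.parent, tree.children, newb, tree.labels,
                     tree.length_unit, dict(tree.annotations))


def transform_vcv(tree: Phylogeny, lam: float = 1.0, delta: float = 1.0,
                  kappa: float = 1.0) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Apply the Pagel transforms in the fixed order kappa -> delta -> lambda.

    Returns (V_transformed, tip depths after kappa/delta, tip labels).  The
    depths returned are what the directional mean structure uses; lambda does
    not affect them.
    """
    _check_transforms(lam, delta, kappa)
    kt = _kappa_tree(tree, kappa)
    V, labels = phylo_vcv(kt)
    if delta != 1.0:
        V = np.power(V, delta, where=V > 0, out=np.zeros_like(V))
    depths = np.diag(V).copy()
    if lam != 1.0:
        off = V - np.diag(np.diag(V))
        V = lam * off + np.diag(np.diag(V))
    return V, depths, labels


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _matnorm_loglik(Y: np.ndarray, M: np.ndarray, L: np.ndarray,
                    logdetV: float, sigma: np.ndarray) -> float:
    """Matrix-normal log density: rows ~ V (cholesky L), columns ~ sigma (2x2)."""
    n = Y.shape[0]
    Z = solve_triangular(L, Y - M, lower=True, check_finite=False)
    S = Z.T @ Z
    det_s = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
    if det_s <= 0:
        return -np.inf
    inv_s = np.array([[sigma[1, 1], -sigma[0, 1]],
                      [-sigma[0, 1], sigma[0, 0]]]) / det_s
    return (-n * math.log(2 * math.pi) - logdetV - 0.5 * n * math.log(det_s)
            - 0.5 * float(np.sum(inv_s * S)))


def loglik(traits: np.ndarray, tree: Phylogeny, model: BMModel) -> float:
    """Log-likelihood of an n x 2 trait matrix (post-order tip rows) under `model`."""
    Y = np.asarray(traits, dtype=float)
    V, depths, _ = transform_vcv(tree, model.lam, model.delta, model.kappa)
    try:
        L = cholesky(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "transformed covariance is singular; try lambda < 1 or add jitter"
        ) from exc
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    M = np.column_stack([
        model.alpha[0] + model.beta[0] * depths,
        model.alpha[1] + model.beta[1] * depths,
    ])
    return _matnorm_loglik(Y, M, L, logdetV, model.sigma)


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class ThermalModel:
    """Two-trait Brownian model of thermal tolerance on a phylogram.

    Parameters
    ----------
    tree : Phylogeny (phylogram recommended; a warning is issued for
        ultrametric input when fitting the directional model).
    traits : TaxonTable with columns ``t_cold_c`` and ``t_warm_c``, or an
        n x 2 array already in post-order tip order.
    model : "A" (random walk) or "B" (directional).
    estimate_delta, estimate_kappa : free the corresponding transform
        (both fixed to 1 by default; lambda is always estimated).
    """

    PARAM_NAMES = ("alpha_cold", "alpha_warm", "beta_cold", "beta_warm",
                   "sigma11", "sigma12", "sigma22", "lambda", "delta", "kappa")

    def __init__(self, tree: Phylogeny, traits, model: str = "B",
                 estimate_delta: bool = False, estimate_kappa: bool = False):
        if model not in ("A", "B"):
            raise ValueError("model must be 'A' or 'B'")
        self.tree = tree
        self.model = model
        self.estimate_delta = estimate_delta
        self.estimate_kappa = estimate_kappa
        if isinstance(traits, TaxonTable):
            frame, _ = join_table(tree, traits, columns=["t_cold_c", "t_warm_c"],
                                  strict=True)
            self.Y = frame.to_numpy(dtype=float)
        else:
            self.Y = np.asarray(traits, dtype=float)
            if self.Y.shape != (len(tree.tips), 2):
                raise ValueError("traits must be n_tips x 2 in post-order")
        bad = [i for i in range(self.Y.shape[0]) if self.Y[i, 0] > self.Y[i, 1]]
        if bad:
            warnings.warn(
                f"T_cold > T_warm for tip rows {bad}; values kept as given",
                stacklevel=2)
        self._base_V, self._base_depths, self.tip_labels = transform_vcv(tree)
        if model == "B" and np.ptp(self._base_depths) < 1e-9 * max(
                self._base_depths.max(), 1.0):
            warnings.warn(
                "tree is ultrametric: the directional trend (beta) is not "
                "identifiable; use a phylogram", stacklevel=2)

    # -- cached covariance pieces per (lam, delta, kappa) -------------------
    def _cov(self, lam: float, delta: float, kappa: float):
        if delta == 1.0 and kappa == 1.0:
            V = self._base_V
            depths = self._base_depths
            if lam != 1.0:
                V = lam * V + (1 - lam) * np.diag(np.diag(V))
        else:
            V, depths, _ = transform_vcv(self.tree, lam, delta, kappa)
        L = cholesky(V, lower=True, check_finite=False)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
        return L, logdetV, depths

    def _loglik_state(self, theta: Dict[str, float], cache: Dict) -> float:
        key = (theta["lambda"], theta["delta"], theta["kappa"])
        if cache.get("key") != key:
            try:
                cache["L"], cache["logdetV"], cache["depths"] = self._cov(*key)
            except np.linalg.LinAlgError:
                return -np.inf
            cache["key"] = key
        L, logdetV, depths = cache["L"], cache["logdetV"], cache["depths"]
        M = np.column_stack([
            theta["alpha_cold"] + theta["beta_cold"] * depths,
            theta["alpha_warm"] + theta["beta_warm"] * depths,
        ])
        sigma = np.array([[theta["sigma11"], theta["sigma12"]],
                          [theta["sigma12"], theta["sigma22"]]])
        return _matnorm_loglik(self.Y, M, L, logdetV, sigma)

    def _theta_to_bm(self, theta: Dict[str, float]) -> BMModel:
        return BMModel(
            model=self.model,
            alpha=(theta["alpha_cold"], theta["alpha_warm"]),
            beta=(theta["beta_cold"], theta["beta_warm"]),
            sigma=np.array([[theta["sigma11"], theta["sigma12"]],
                            [theta["sigma12"], theta["sigma22"]]]),
            lam=theta["lambda"], delta=theta["delta"], kappa=theta["kappa"],
        )

    def loglik(self, model: BMModel) -> float:
        return loglik(self.Y, self.tree, model)

    # -- maximum likelihood -------------------------------------------------
    def _pack_names(self) -> List[str]:
        names = ["alpha_cold", "alpha_warm"]
        if self.model == "B":
            names += ["beta_cold", "beta_warm"]
        names += ["log_s11", "log_s22", "atanh_rho", "lambda"]
        if self.estimate_delta:
            names.append("log_delta")
        if self.estimate_kappa:
            names.append("kappa")
        return names

    def _unpack(self, x: np.ndarray) -> Dict[str, float]:
        names = self._pack_names()
        theta = {
            "beta_cold": 0.0, "beta_warm": 0.0,
            "delta": 1.0, "kappa": 1.0,
        }
        vals = dict(zip(names, x))
        theta["alpha_cold"] = vals["alpha_cold"]
        theta["alpha_warm"] = vals["alpha_warm"]
        if self.model == "B":
            theta["beta_cold"] = vals["beta_cold"]
            theta["beta_warm"] = vals["beta_warm"]
        s11 = math.exp(vals["log_s11"])
        s22 = math.exp(vals["log_s22"])
        rho = math.tanh(vals["atanh_rho"])
        theta["sigma11"] = s11
        theta["sigma22"] = s22
        theta["sigma12"] = rho * math.sqrt(s11 * s22)
        theta["lambda"] = vals["lambda"]
        if self.estimate_delta:
            theta["delta"] = math.exp(vals["log_delta"])
        if self.estimate_kappa:
            theta["kappa"] = vals["kappa"]
        return theta

    def fit(self, starts: int = 3, seed: int = 0) -> "ThermalMLFit":
        """Maximum-likelihood fit (multi-start quasi-Newton)."""
        names = self._pack_names()
        depth_scale = max(self._base_depths.mean(), 1e-12)
        y_mean = self.Y.mean(axis=0)
        y_var = max(self.Y.var(axis=0).mean(), 1e-6)
        rng = np.random.default_rng(seed)
        bounds = []
        for nm in names:
            if nm == "lambda":
                bounds.append((0.0, 1.0))
            elif nm in ("log_s11", "log_s22"):
                bounds.append((math.log(y_var) - 14, math.log(y_var / depth_scale) + 14))
            elif nm == "atanh_rho":
                bounds.append((-5.0, 5.0))
            elif nm == "log_delta":
                bounds.append((math.log(1e-2), math.log(1e2)))
            elif nm == "kappa":
                bounds.append((0.0, 3.0))
            else:
                bounds.append((None, None))
        cache: Dict = {}

        def neg(x: np.ndarray) -> float:
            ll = self._loglik_state(self._unpack(x), cache)
            return -ll if np.isfinite(ll) else 1e12

        best = None
        for s in range(starts):
            x0 = []
            for nm in names:
                if nm == "alpha_cold":
                    x0.append(y_mean[0] + (rng.normal(0, 2) if s else 0))
                elif nm == "alpha_warm":
                    x0.append(y_mean[1] + (rng.normal(0, 2) if s else 0))
                elif nm in ("beta_cold", "beta_warm"):
                    x0.append(0.0 if not s else rng.normal(0, 1) / depth_scale)
                elif nm in ("log_s11", "log_s22"):
                    x0.append(math.log(y_var / depth_scale) + (rng.normal(0, 1) if s else 0))
                elif nm == "atanh_rho":
                    x0.append(0.0)
                elif nm == "lambda":
                    x0.append(0.9 if not s else rng.uniform(0.2, 1.0))
                elif nm == "log_delta":
                    x0.append(0.0)
                elif nm == "kappa":
                    x0.append(1.0)
            res = minimize(neg, np.array(x0), method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 1500})
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None
        theta = self._unpack(best.x)
        return ThermalMLFit(model=self._theta_to_bm(theta),
                            loglik=-float(best.fun),
                            n_params=len(names), converged=bool(best.success))

    # -- MCMC ---------------------------------------------------------------
    def fit_mcmc(self, config: Optional[MCMCConfig] = None,
                 power: float = 1.0) -> "ThermalResults":
        """Metropolis–Hastings posterior sampling.

        `power` tempers the likelihood (used internally by stepping-stone
        marginal-likelihood estimation); the default 1.0 is the posterior.
        """
        cfg = config or MCMCConfig()
        rng = np.random.default_rng(cfg.seed)
        y_mean = self.Y.mean(axis=0)
        y_var = max(self.Y.var(axis=0).mean(), 1e-6)
        depth_scale = max(self._base_depths.mean(), 1e-12)
        sig0 = y_var / depth_scale
        lo_sig, hi_sig = sig0 * 1e-6, sig0 * 1e6
        alpha_sd = 1e3  # weakly-informative normal prior on alpha and beta

        theta = {
            "alpha_cold": float(y_mean[0]), "alpha_warm": float(y_mean[1]),
            "beta_cold": 0.0, "beta_warm": 0.0,
            "sigma11": sig0, "sigma22": sig0, "sigma12": 0.0,
            "lambda": 0.9, "delta": 1.0, "kappa": 1.0,
        }
        rho = 0.0
        cache: Dict = {}

        def log_prior(th: Dict[str, float], rho_: float) -> float:
            lp = 0.0
            for k in ("alpha_cold", "alpha_warm", "beta_cold", "beta_warm"):
                lp += -0.5 * (th[k] / alpha_sd) ** 2
            if not (lo_sig <= th["sigma11"] <= hi_sig):
                return -np.inf
            if not (lo_sig <= th["sigma22"] <= hi_sig):
                return -np.inf
            if not (-1 < rho_ < 1):
                return -np.inf
            if not (0.0 <= th["lambda"] <= 1.0):
                return -np.inf
            if not (1e-2 <= th["delta"] <= 1e2):
                return -np.inf
            if not (0.0 <= th["kappa"] <= 3.0):
                return -np.inf
            # log-uniform prior on the sigma diagonals
            lp += -math.log(th["sigma11"]) - math.log(th["sigma22"])
            return lp

        cur_ll = self._loglik_state(theta, cache)
        cur_lp = log_prior(theta, rho)
        if not np.isfinite(cur_ll):
            raise RuntimeError("initial state has zero likelihood")

        blocks = ["alpha", "sigma", "lambda"]
        if self.model == "B":
            blocks.insert(1, "beta")
        if self.estimate_delta:
            blocks.append("delta")
        if self.estimate_kappa:
            blocks.append("kappa")
        accept = {b: 0 for b in blocks}
        tries = {b: 0 for b in blocks}

        records: List[List[float]] = []
        lls: List[float] = []
        for it in range(cfg.iterations):
            for b in blocks:
                prop = dict(theta)
                rho_p = rho
                if b == "alpha":
                    prop["alpha_cold"] += rng.normal(0, cfg.scale_alpha)
                    prop["alpha_warm"] += rng.normal(0, cfg.scale_alpha)
                elif b == "beta":
                    prop["beta_cold"] += rng.normal(0, cfg.scale_beta)
                    prop["beta_warm"] += rng.normal(0, cfg.scale_beta)
                elif b == "sigma":
                    prop["sigma11"] = theta["sigma11"] * math.exp(rng.normal(0, cfg.scale_logsig))
                    prop["sigma22"] = theta["sigma22"] * math.exp(rng.normal(0, cfg.scale_logsig))
                    rho_p = rho + rng.normal(0, cfg.scale_rho)
                    prop["sigma12"] = rho_p * math.sqrt(prop["sigma11"] * prop["sigma22"])
                elif b == "lambda":
                    prop["lambda"] = theta["lambda"] + rng.normal(0, cfg.scale_lam)
                elif b == "delta":
                    prop["delta"] = theta["delta"] * math.exp(rng.normal(0, cfg.scale_shape))
                elif b == "kappa":
                    prop["kappa"] = theta["kappa"] + rng.normal(0, cfg.scale_shape)
                lp = log_prior(prop, rho_p)
                tries[b] += 1
                key_changed = (prop["lambda"], prop["delta"], prop["kappa"]) != (
                    theta["lambda"], theta["delta"], theta["kappa"])
                if np.isfinite(lp):
                    ll = self._loglik_state(prop, cache)
                    ratio = power * (ll - cur_ll) + lp - cur_lp
                    # symmetric proposals except the log-scale sigma moves
                    if b == "sigma":
                        ratio += (math.log(prop["sigma11"]) - math.log(theta["sigma11"])
                                  + math.log(prop["sigma22"]) - math.log(theta["sigma22"]))
                    if math.log(rng.uniform()) < ratio:
                        theta, rho, cur_ll, cur_lp = prop, rho_p, ll, lp
                        accept[b] += 1
                    elif key_changed:
                        # drop the cached covariance built for the rejected move
                        cache["key"] = None
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.sample_period == 0:
                records.append([theta[k] for k in self.PARAM_NAMES])
                lls.append(cur_ll)

        if not records:
            raise RuntimeError("no samples retained; check iterations/burn_in")
        samples = pd.DataFrame(records, columns=list(self.PARAM_NAMES))
        samples["loglik"] = lls
        acc = {b: accept[b] / max(tries[b], 1) for b in blocks}
        if all(a == 0 for a in acc.values()):
            raise RuntimeError(
                "chain accepted no proposals; reduce proposal scales")
        return ThermalResults(model=self, samples=samples, config=cfg,
                              acceptance=acc)

    # stepping-stone marginal likelihood -----------------------------------
    def stepping_stone_logml(self, config: Optional[MCMCConfig] = None,
                             n_rungs: int = 8) -> float:
        """Stepping-stone estimate of the log marginal likelihood.

        Runs short power-posterior chains at beta_k = (k/K)^(1/0.3) and sums
        the importance-ratio estimates between consecutive rungs.
        """
        cfg = config or MCMCConfig(iterations=20_000, burn_in=2_000,
                                   sample_period=20)
        powers = np.array([(k / n_rungs) ** (1 / 0.3) for k in range(n_rungs + 1)])
        logml = 0.0
        for k in range(n_rungs):
            rcfg = replace(cfg, seed=cfg.seed + 1000 * k)
            res = self.fit_mcmc(rcfg, power=float(powers[k]))
            ll = res.samples["loglik"].to_numpy()
            dp = powers[k + 1] - powers[k]
            m = np.max(ll)
            logml += m * dp + math.log(np.mean(np.exp(dp * (ll - m))))
        return float(logml)


@dataclass
class ThermalMLFit:
    model: BMModel
    loglik: float
    n_params: int
    converged: bool


@dataclass
class ThermalResults:
    """Posterior samples from :meth:`ThermalModel.fit_mcmc` plus summaries."""

    model: ThermalModel
    samples: pd.DataFrame
    config: MCMCConfig
    acceptance: Dict[str, float]

    def posterior_mean(self, name: str) -> float:
        return float(self.samples[name].mean())

    def summary(self) -> str:
        lines = [
            f"Thermal tolerance Brownian model {self.model.model} "
            f"({len(self.samples)} posterior samples)",
            f"{'parameter':>12} {'mean':>10} {'sd':>10} {'2.5%':>10} {'97.5%':>10}",
        ]
        for name in self.model.PARAM_NAMES:
            col = self.samples[name]
            lines.append(
                f"{name:>12} {col.mean():>10.4f} {col.std():>10.4f} "
                f"{col.quantile(0.025):>10.4f} {col.quantile(0.975):>10.4f}")
        lines.append("acceptance: " + ", ".join(
            f"{b}={a:.2f}" for b, a in self.acceptance.items()))
        return "\n".join(lines)

    # -- ancestral reconstruction ------------------------------------------
    def ancestral_states(self, nodes: Iterable[int],
                         max_draws: int = 1000) -> List[AncestralTolerance]:
        """Posterior ancestral (T_cold, T_warm) at interior nodes.

        For each retained parameter draw the node state is sampled from its
        exact conditional normal given the tip data; lambda scales node-tip
        covariances like any other off-diagonal entry.
        """
        tree = self.model.tree
        nodes = list(nodes)
        for n in nodes:
            if tree.is_tip(n):
                raise ValueError(f"node {n} is a tip; ancestral state is observed")
        tips = list(tree.tips)
        tip_pos = {t: i for i, t in enumerate(tips)}
        # mrca(node, tip) indices, computed once
        below = tree.node_tips()
        anc_cache: Dict[int, np.ndarray] = {}
        for node in nodes:
            mr = np.zeros(len(tips), dtype=int)
            in_clade = set(below[node])
            anc_chain = [node] + tree.ancestors(node)
            anc_set = {a: i for i, a in enumerate(anc_chain)}
            for t in tips:
                if t in in_clade:
                    mr[tip_pos[t]] = node
                else:
                    # walk up from the tip until hitting the node's ancestor chain
                    p = t
                    while p not in anc_set:
                        p = int(tree.parent[p])
                    mr[tip_pos[t]] = p
            anc_cache[node] = mr

        sub = self.samples
        if len(sub) > max_draws:
            step = len(sub) // max_draws
            sub = sub.iloc[::step]
        rng = np.random.default_rng(self.config.seed + 7)
        Y = self.model.Y
        out: List[AncestralTolerance] = []
        draws_by_node: Dict[int, List[np.ndarray]] = {n: [] for n in nodes}
        for _, row in sub.iterrows():
            lam, delta, kappa = row["lambda"], row["delta"], row["kappa"]
            kt = _kappa_tree(tree, kappa)
            depths_k = kt.depths()
            if delta != 1.0:
                with np.errstate(invalid="ignore"):
                    dtrans = np.where(depths_k > 0, depths_k ** delta, 0.0)
            else:
                dtrans = depths_k
            V, tip_depths, _ = transform_vcv(tree, lam, delta, kappa)
            cho = cho_factor(V, lower=True, check_finite=False)
            sigma = np.array([[row["sigma11"], row["sigma12"]],
                              [row["sigma12"], row["sigma22"]]])
            M = np.column_stack([
                row["alpha_cold"] + row["beta_cold"] * tip_depths,
                row["alpha_warm"] + row["beta_warm"] * tip_depths,
            ])
            resid = Y - M
            Vinv_resid = cho_solve(cho, resid)
            for node in nodes:
                c = lam * dtrans[anc_cache[node]]
                v_node = dtrans[node]
                Vinv_c = cho_solve(cho, c)
                mean_node = np.array([
                    row["alpha_cold"] + row["beta_cold"] * v_node,
                    row["alpha_warm"] + row["beta_warm"] * v_node,
                ]) + c @ Vinv_resid
                var_scalar = max(v_node - float(c @ Vinv_c), 0.0)
                cov = var_scalar * sigma
                draw = rng.multivariate_normal(mean_node, cov)
                draws_by_node[node].append(draw)
        for node in nodes:
            arr = np.array(draws_by_node[node])
            mc, mw = arr.mean(axis=0)
            out.append(AncestralTolerance(
                node=node,
                mean_cold=float(mc), mean_warm=float(mw),
                ci_cold=(float(np.percentile(arr[:, 0], 2.5)),
                         float(np.percentile(arr[:, 0], 97.5))),
                ci_warm=(float(np.percentile(arr[:, 1], 2.5)),
                         float(np.percentile(arr[:, 1], 97.5))),
                samples=arr,
                ordering_violated=bool(mc > mw),
            ))
        return out


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    best: str  # "A" | "B"
    log_bayes_factor: Optional[float] = None  # log BF in favour of B

    def summary(self) -> str:
        s = (f"LRT B vs A: stat={self.lrt_stat:.4f}, df={self.lrt_df}, "
             f"p={self.lrt_p:.4g} -> model {self.best}")
        if self.log_bayes_factor is not None:
            s += f"; log Bayes factor (B over A) = {self.log_bayes_factor:.3f}"
        return s


def compare_models(fit_a: ThermalMLFit, fit_b: ThermalMLFit,
                   logml_a: Optional[float] = None,
                   logml_b: Optional[float] = None,
                   alpha: float = 0.05) -> ModelComparison:
    """Likelihood-ratio test of directional (B) against random-walk (A).

    Optionally attaches a stepping-stone log Bayes factor when marginal
    likelihoods for both models are supplied.
    """
    if fit_a.model.model != "A" or fit_b.model.model != "B":
        raise ValueError("pass the model-A fit first and the model-B fit second")
    df = fit_b.n_params - fit_a.n_params
    if df <= 0:
        raise ValueError("model B must have extra parameters")
    stat = max(2.0 * (fit_b.loglik - fit_a.loglik), 0.0)
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    best = "B" if p < alpha else "A"
    lbf = None
    if logml_a is not None and logml_b is not None:
        lbf = float(logml_b - logml_a)
    return ModelComparison(lrt_stat=stat, lrt_df=df, lrt_p=p, best=best,
                           log_bayes_factor=lbf)
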