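"""Fully Bayesian MCMC fitting of the spatial gender-age-period-cohort model.

The sampler is a Metropolis-within-Gibbs scheme.  Each Gaussian Markov
random field block (period, age and cohort walks per gender, the spatial
ICAR effect, and the space-time interaction) is updated jointly using a
Gaussian approximation to its full conditional built from one Newton step
on the Poisson log-likelihood at the current state (a Gamerman-type
weighted-least-squares proposal), accepted or rejected by a
Metropolis-Hastings step with the exact proposal correction.  Sum-to-zero
constraints are enforced inside the sampler by conditioning-by-kriging:
every block proposal is conditioned on its constraint system before the
accept step, so every retained draw satisfies the constraints exactly.

Precision hyperparameters are updated by adaptive random-walk Metropolis
on the log-precision scale, under either penalised-complexity or bounded
uniform-on-SD hyperpriors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import arviz as az
import numpy as np
import pandas as pd
import scipy.linalg

from . import __version__ as _pkg_version
from .data_model import AdjacencyGraph, MortalityDataset
from .errors import GapcError, InferenceError, StructureError
from .structure import (
    ConstraintSystem,
    EffectSet,
    ModelSpec,
    cohort_index_grid,
    delta_constraint_matrix,
    icar_precision,
    interaction_precision,
    linear_predictor,
    rw_precision,
)

__all__ = [
    "PosteriorResult",
    "fit_gapc",
    "exceedance_probability",
    "constrain",
]


def exceedance_probability(samples, threshold: float) -> float:
    """Fraction of posterior draws strictly greater than ``threshold``."""
    s = np.asarray(samples, dtype=float).ravel()
    if s.size == 0:
        raise GapcError("exceedance probability needs at least one draw")
    return float(np.mean(s > threshold))


def constrain(effect: np.ndarray, constraints: ConstraintSystem | np.ndarray) -> np.ndarray:
    """Orthogonal projection of an effect vector onto {x : Cx = 0}.

    Idempotent; the least-squares solution to min ||x - effect|| s.t. Cx=0.
    """
    x = np.asarray(effect, dtype=float)
    C = constraints.matrix if isinstance(constraints, ConstraintSystem) else np.atleast_2d(constraints)
    flat = x.ravel()
    if C.shape[1] != flat.size:
        raise StructureError(f"constraint matrix has {C.shape[1]} columns for a vector of size {flat.size}")
    # lstsq handles redundant (rank-deficient) constraint rows
    return (flat - C.T @ np.linalg.lstsq(C @ C.T, C @ flat, rcond=None)[0]).reshape(x.shape)


# --------------------------------------------------------------------------
# sampler internals
# --------------------------------------------------------------------------


class _Prec:
    """Symmetric positive-definite precision with diagonal fast path."""

    def __init__(self, mat: np.ndarray | None, diag: np.ndarray | None):
        self.mat = mat
        if diag is not None:
            if np.any(diag <= 0):
                raise InferenceError("non-PD proposal precision")
            self.diag = diag
            self.cho = None
        else:
            self.diag = None
            try:
                self.cho = scipy.linalg.cho_factor(mat, lower=True)
            except scipy.linalg.LinAlgError as e:  # pragma: no cover
                raise InferenceError(f"proposal precision not PD: {e}") from e

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self.diag is not None:
            return b / (self.diag if b.ndim == 1 else self.diag[:, None])
        return scipy.linalg.cho_solve(self.cho, b)

    def sample(self, rng: np.random.Generator, mean: np.ndarray) -> np.ndarray:
        xi = rng.standard_normal(mean.size)
        if self.diag is not None:
            return mean + xi / np.sqrt(self.diag)
        L = self.cho[0]
        return mean + scipy.linalg.solve_triangular(L, xi, lower=True, trans="T")

    def logdet(self) -> float:
        if self.diag is not None:
            return float(np.sum(np.log(self.diag)))
        return 2.0 * float(np.sum(np.log(np.diag(self.cho[0]))))

    def quad(self, v: np.ndarray) -> float:
        if self.diag is not None:
            return float(v @ (self.diag * v))
        return float(v @ (self.mat @ v))


def _constrained_logq(x: np.ndarray, m: np.ndarray, P: _Prec, A: np.ndarray | None) -> float:
    """Log density (up to a shared constant) of N(m, P^-1) conditioned on Ax=0."""
    out = 0.5 * P.logdet() - 0.5 * P.quad(x - m)
    if A is not None:
        S = A @ P.solve(A.T)  # r x r
        Am = A @ m
        sign, ld = np.linalg.slogdet(S)
        out += 0.5 * ld + 0.5 * float(Am @ np.linalg.solve(S, Am))
    return out


def _krige(y: np.ndarray, P: _Prec, A: np.ndarray | None) -> np.ndarray:
    """Condition a free Gaussian draw on Ax = 0 (conditioning by kriging)."""
    if A is None:
        return y
    S = A @ P.solve(A.T)
    return y - P.solve(A.T @ np.linalg.solve(S, A @ y))


@dataclass
class _Block:
    """One jointly-updated latent block."""

    name: str
    effect: str            # attribute of EffectSet
    gender: int | None     # row of the (G, L) effect array, or None
    n: int
    Q: np.ndarray | None   # structure matrix (None -> zero; beta uses fixed prior)
    Q_diag: np.ndarray | None  # diagonal representation when Q is diagonal
    A: np.ndarray | None   # constraint rows with redundancy removed
    rank_z: int            # rank of the structure restricted to the constraint space
    tau_key: str | None    # hyperparameter name; None for the intercept block
    fixed_prec_diag: np.ndarray | None = None  # proper Gaussian prior (beta)
    accepted: int = 0
    proposed: int = 0

    def get(self, eff: EffectSet) -> np.ndarray:
        arr = getattr(eff, self.effect)
        return arr[self.gender].ravel().copy() if self.gender is not None else arr.ravel().copy()

    def put(self, eff: EffectSet, x: np.ndarray) -> None:
        arr = getattr(eff, self.effect)
        if self.gender is not None:
            arr[self.gender] = x.reshape(arr[self.gender].shape)
        else:
            arr[...] = x.reshape(arr.shape)

    def prior_quad(self, x: np.ndarray) -> float:
        if self.Q_diag is not None:
            return float(x @ (self.Q_diag * x))
        if self.Q is not None:
            return float(x @ (self.Q @ x))
        return float(x @ (self.fixed_prec_diag * x))

    def prec(self, tau: float, lik_hess: np.ndarray) -> _Prec:
        if self.Q_diag is not None:
            return _Prec(None, tau * self.Q_diag + lik_hess)
        if self.Q is not None:
            M = tau * self.Q + np.diag(lik_hess)
            return _Prec(M, None)
        return _Prec(None, self.fixed_prec_diag + lik_hess)


class _GapcSampler:
    """Model state and update machinery for one MCMC chain family."""

    def __init__(
        self,
        dataset: MortalityDataset,
        graph: AdjacencyGraph | None,
        spec: ModelSpec,
        fix_precisions: dict[str, float] | None = None,
    ):
        if dataset.dims.shape != spec.dims.shape:
            raise StructureError("dataset and model dims disagree")
        self.dataset = dataset
        self.spec = spec
        self.graph = graph
        dims = spec.dims
        self.C = dataset.deaths.astype(float)
        self.logn = np.log(dataset.population)
        self.kgrid = cohort_index_grid(dims)
        self.fix_precisions = dict(fix_precisions or {})

        needs_graph = "phi" in spec.effects or spec.interaction_type in ("III", "IV")
        if needs_graph:
            if graph is None:
                raise StructureError("model includes a spatial structure but no graph was given")
            if graph.n_nodes != dims.A:
                raise StructureError(
                    f"graph has {graph.n_nodes} nodes but the dataset has {dims.A} areas"
                )

        self.blocks: list[_Block] = []
        self._build_blocks()
        self.tau_keys = sorted(
            {b.tau_key for b in self.blocks if b.tau_key is not None} - set(self.fix_precisions)
        )

    # -- block construction ----------------------------------------------
    def _build_blocks(self) -> None:
        dims, spec = self.spec.dims, self.spec
        beta_prec = np.full(dims.G, 1.0 / spec.priors.intercept_variance)
        self.blocks.append(
            _Block("beta", "beta", None, dims.G, None, None, None, 0, None,
                   fixed_prec_diag=beta_prec)
        )
        lengths = {"alpha": dims.T, "gamma": dims.I, "kappa": dims.K}
        for eff in ("alpha", "gamma", "kappa"):
            if eff not in spec.effects:
                continue
            Q = rw_precision(lengths[eff], spec.rw_order[eff]).matrix
            ones = np.ones((1, lengths[eff]))
            rank_z = _restricted_rank(Q, ones)
            for g in range(dims.G):
                key = f"tau_{eff}" if spec.shared_precision_across_genders else f"tau_{eff}_{g}"
                self.blocks.append(
                    _Block(f"{eff}[{g}]", eff, g, lengths[eff], Q, None, ones, rank_z, key)
                )
        if "phi" in spec.effects:
            Q = icar_precision(self.graph).matrix
            ones = np.ones((1, dims.A))
            self.blocks.append(
                _Block("phi", "phi", None, dims.A, Q, None, ones,
                       _restricted_rank(Q, ones), "tau_phi")
            )
        if spec.interaction_type != "none":
            A_c = delta_constraint_matrix(spec.interaction_type, dims.A, dims.T)
            # drop one redundant row of the type-IV system (rank A + T - 1)
            if spec.interaction_type == "IV":
                A_c = A_c[:-1]
            n = dims.A * dims.T
            if spec.interaction_type == "I":
                self.blocks.append(
                    _Block("delta", "delta", None, n, None, np.ones(n), A_c,
                           _restricted_rank(np.eye(n), A_c), "tau_delta")
                )
            else:
                Qs = icar_precision(self.graph) if spec.interaction_type in ("III", "IV") else None
                Qt = rw_precision(dims.T, 1) if spec.interaction_type in ("II", "IV") else None
                from .structure import StructureMatrix

                Qsm = Qs if Qs is not None else StructureMatrix(np.eye(dims.A), dims.A)
                Qtm = Qt if Qt is not None else StructureMatrix(np.eye(dims.T), dims.T)
                Q = interaction_precision(spec.interaction_type, Qsm, Qtm).matrix
                self.blocks.append(
                    _Block("delta", "delta", None, n, Q, None, A_c,
                           _restricted_rank(Q, A_c), "tau_delta")
                )

    # -- likelihood pieces -------------------------------------------------
    def log_mu(self, eff: EffectSet) -> np.ndarray:
        return linear_predictor(eff, self.dataset, self.spec)[1]

    def loglik(self, log_mu: np.ndarray) -> float:
        # Poisson log-likelihood up to the log(C!) constant
        return float(np.sum(self.C * log_mu) - np.sum(np.exp(log_mu)))

    def _agg(self, block: _Block, arr: np.ndarray) -> np.ndarray:
        """Sum a (G, A, I, T) cell array onto the block's coordinates."""
        dims = self.spec.dims
        if block.effect == "beta":
            return arr.sum(axis=(1, 2, 3))
        if block.effect == "alpha":
            return arr[block.gender].sum(axis=(0, 1))
        if block.effect == "gamma":
            return arr[block.gender].sum(axis=(0, 2))
        if block.effect == "kappa":
            per_it = arr[block.gender].sum(axis=0)  # (I, T)
            return np.bincount(self.kgrid.ravel(), weights=per_it.ravel(), minlength=dims.K)
        if block.effect == "phi":
            return arr.sum(axis=(0, 2, 3))
        if block.effect == "delta":
            return arr.sum(axis=(0, 2)).ravel()  # (A, T) -> area-major
        raise StructureError(block.effect)

    def _prior_grad(self, block: _Block, tau: float, x: np.ndarray) -> np.ndarray:
        if block.Q_diag is not None:
            return -tau * (block.Q_diag * x)
        if block.Q is not None:
            return -tau * (block.Q @ x)
        return -block.fixed_prec_diag * x

    def _block_logpost(self, block: _Block, tau: float, x: np.ndarray, log_mu: np.ndarray) -> float:
        scale = tau if block.tau_key is not None else 1.0
        return self.loglik(log_mu) - 0.5 * scale * block.prior_quad(x)

    def _conditional_mode(
        self, block: _Block, eff: EffectSet, tau: float, log_mu: np.ndarray,
        max_iter: int = 25, tol: float = 1e-9,
    ) -> tuple[np.ndarray, _Prec, np.ndarray]:
        """Newton iteration (with step halving) to the block's conditional mode.

        The mode depends only on the other blocks' current values, so the
        resulting Gaussian is a valid independence proposal for this block.
        Returns (mode, precision at mode, original block value).
        """
        x0 = block.get(eff)
        x = x0
        f = self._block_logpost(block, tau, x, log_mu)
        P = None
        for _ in range(max_iter):
            mu = np.exp(log_mu)
            grad = self._agg(block, self.C - mu) + self._prior_grad(block, tau, x)
            hess = np.maximum(self._agg(block, mu), 1e-12)
            P = block.prec(tau, hess)
            step = P.solve(grad)
            if np.max(np.abs(step)) < tol:
                break
            t = 1.0
            for _ in range(20):  # backtracking on the conditional log-posterior
                x_try = x + t * step
                block.put(eff, x_try)
                lm_try = self.log_mu(eff)
                f_try = self._block_logpost(block, tau, x_try, lm_try)
                if np.isfinite(f_try) and f_try >= f - 1e-12:
                    x, f, log_mu = x_try, f_try, lm_try
                    break
                t *= 0.5
            else:
                break  # no improving step; accept current point as mode
        if P is None:  # pragma: no cover
            mu = np.exp(log_mu)
            P = block.prec(tau, np.maximum(self._agg(block, mu), 1e-12))
        block.put(eff, x0)
        return x, P, x0

    # -- one MH update of a latent block -----------------------------------
    def update_block(
        self, block: _Block, eff: EffectSet, log_mu: np.ndarray,
        taus: dict[str, float], rng: np.random.Generator,
    ) -> np.ndarray:
        """Independence MH step from the Gaussian approximation at the
        conditional mode, with the proposal conditioned on the block's
        sum-to-zero constraints by kriging."""
        tau = 1.0 if block.tau_key is None else taus.get(
            block.tau_key, self.fix_precisions.get(block.tau_key, np.nan)
        )
        x = block.get(eff)
        mode, P, _ = self._conditional_mode(block, eff, tau, log_mu)
        y = P.sample(rng, mode)
        x_new = _krige(y, P, block.A)

        block.put(eff, x_new)
        log_mu2 = self.log_mu(eff)
        log_acc = (
            self._block_logpost(block, tau, x_new, log_mu2)
            - self._block_logpost(block, tau, x, log_mu)
            + _constrained_logq(x, mode, P, block.A)
            - _constrained_logq(x_new, mode, P, block.A)
        )
        block.proposed += 1
        if np.isfinite(log_acc) and np.log(rng.uniform()) < log_acc:
            block.accepted += 1
            return log_mu2
        block.put(eff, x)
        return log_mu

    # -- hyperparameter update ---------------------------------------------
    def tau_logtarget(self, key: str, tau: float, eff: EffectSet) -> float:
        if tau <= 0:
            return -np.inf
        pri = self.spec.priors.logdensity(tau)
        if not np.isfinite(pri):
            return -np.inf
        out = pri
        for b in self.blocks:
            if b.tau_key == key:
                x = b.get(eff)
                out += 0.5 * b.rank_z * np.log(tau) - 0.5 * tau * b.prior_quad(x)
        return out

    def update_taus(
        self, eff: EffectSet, taus: dict[str, float], steps: dict[str, float],
        rng: np.random.Generator, adapt: bool, it: int,
    ) -> None:
        for key in self.tau_keys:
            theta = np.log(taus[key])
            # hard numerical bounds on log-precision to keep tau*Q representable
            theta_new = np.clip(theta + steps[key] * rng.standard_normal(), -18.0, 27.0)
            # Jacobian of tau = exp(theta) adds +theta to each side
            cur = self.tau_logtarget(key, np.exp(theta), eff) + theta
            new = self.tau_logtarget(key, np.exp(theta_new), eff) + theta_new
            acc = np.log(rng.uniform()) < new - cur
            if acc:
                taus[key] = float(np.exp(theta_new))
            if adapt:
                # Robbins-Monro on the log step toward 44% acceptance
                target = 0.44
                steps[key] = float(np.exp(
                    np.log(steps[key]) + ((1.0 if acc else 0.0) - target) / max(1.0, it ** 0.6)
                ))


def _restricted_rank(Q: np.ndarray, A: np.ndarray) -> int:
    """Rank of x'Qx restricted to {Ax = 0} (positive eigenvalues of Z'QZ)."""
    Z = scipy.linalg.null_space(np.atleast_2d(A))
    Qz = Z.T @ Q @ Z
    w = np.linalg.eigvalsh(Qz)
    thresh = 1e-8 * max(w[-1] if w.size else 1.0, 1.0)
    return int(np.sum(w >= thresh))


# --------------------------------------------------------------------------
# result container
# --------------------------------------------------------------------------


@dataclass
class PosteriorResult:
    """Posterior draws, summaries and diagnostics from :func:`fit_gapc`.

    ``samples`` maps each effect name (and each precision hyperparameter
    ``tau_*``) to an array of shape (chains, draws, ...).
    """

    samples: dict
    spec: ModelSpec
    seed: int
    chains: int
    iterations: int
    warmup: int
    acceptance: dict = field(default_factory=dict)

    # -- access -------------------------------------------------------------
    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled over chains: shape (total_draws, ...)."""
        s = self.samples[name]
        return s.reshape((-1,) + s.shape[2:])

    @property
    def n_draws(self) -> int:
        return self.samples["beta"].shape[0] * self.samples["beta"].shape[1]

    def effect_sets(self) -> list[EffectSet]:
        """One EffectSet per pooled draw (views where possible)."""
        names = ("beta", "alpha", "gamma", "kappa", "phi", "delta")
        pooled = {n: self.pooled(n) for n in names}
        return [EffectSet(**{n: pooled[n][s] for n in names}) for s in range(self.n_draws)]

    def posterior_mean_effects(self) -> EffectSet:
        return EffectSet(**{
            n: self.pooled(n).mean(axis=0)
            for n in ("beta", "alpha", "gamma", "kappa", "phi", "delta")
        })

    def log_rate_draws(self, dataset: MortalityDataset) -> np.ndarray:
        """Per-draw log-rate grid, shape (draws, G, A, I, T)."""
        kgrid = cohort_index_grid(self.spec.dims)
        b = self.pooled("beta")[:, :, None, None, None]
        a = self.pooled("alpha")[:, :, None, None, :]
        g = self.pooled("gamma")[:, :, None, :, None]
        k = self.pooled("kappa")[:, :, kgrid][:, :, None, :, :]
        p = self.pooled("phi")[:, None, :, None, None]
        d = self.pooled("delta")[:, None, :, None, :]
        return b + a + g + k + p + d

    # -- summaries ------------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Median/mean/SD/95% interval plus ESS and split-chain R-hat per scalar."""
        rows = []
        idata = az.from_dict(posterior={k: v for k, v in self.samples.items()})
        ess = az.ess(idata)
        rhat = az.rhat(idata) if self.chains > 1 else None
        for name, arr in self.samples.items():
            pooled = arr.reshape((-1,) + arr.shape[2:])
            flat = pooled.reshape(pooled.shape[0], -1)
            e = np.asarray(ess[name]).reshape(-1)
            r = np.asarray(rhat[name]).reshape(-1) if rhat is not None else np.full(flat.shape[1], np.nan)
            qs = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
            for j in range(flat.shape[1]):
                idx = np.unravel_index(j, pooled.shape[1:]) if pooled.ndim > 1 else ()
                label = name + ("[" + ",".join(map(str, idx)) + "]" if idx else "")
                rows.append({
                    "parameter": label,
                    "mean": flat[:, j].mean(),
                    "sd": flat[:, j].std(ddof=1),
                    "median": qs[1, j],
                    "q2.5": qs[0, j],
                    "q97.5": qs[2, j],
                    "ess": e[j],
                    "rhat": r[j],
                })
        return pd.DataFrame(rows)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Write a result bundle: manifest.json + summary.csv + samples.npz."""
        import os

        os.makedirs(path, exist_ok=True)
        np.savez_compressed(os.path.join(path, "samples.npz"), **self.samples)
        self.summary().to_csv(os.path.join(path, "summary.csv"), index=False)
        manifest = {
            "seed": self.seed,
            "chains": self.chains,
            "iterations": self.iterations,
            "warmup": self.warmup,
            "spec": self.spec.to_dict(),
            "package_version": _pkg_version,
            "acceptance": self.acceptance,
        }
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, path) -> "PosteriorResult":
        import os

        with open(os.path.join(path, "manifest.json")) as fh:
            manifest = json.load(fh)
        with np.load(os.path.join(path, "samples.npz")) as npz:
            samples = {k: npz[k] for k in npz.files}
        return cls(
            samples=samples,
            spec=ModelSpec.from_dict(manifest["spec"]),
            seed=manifest["seed"],
            chains=manifest["chains"],
            iterations=manifest["iterations"],
            warmup=manifest["warmup"],
            acceptance=manifest.get("acceptance", {}),
        )


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------


def fit_gapc(
    dataset: MortalityDataset,
    graph: AdjacencyGraph | None,
    spec: ModelSpec,
    chains: int = 4,
    iterations: int = 5000,
    warmup: int | None = None,
    seed: int = 0,
    fix_precisions: dict[str, float] | None = None,
    init_tau: float = 100.0,
) -> PosteriorResult:
    """Run the MCMC sampler and return posterior draws and summaries.

    ``iterations`` is the total per-chain count; the first half (or
    ``warmup``) is discarded and used for step-size adaptation.  Runs are
    bit-reproducible given (seed, chains, iterations).
    """
    if warmup is None:
        warmup = iterations // 2
    if not (0 < warmup < iterations):
        raise GapcError("need 0 < warmup < iterations")
    sampler = _GapcSampler(dataset, graph, spec, fix_precisions)
    dims = spec.dims

    keep = iterations - warmup
    store = {
        "beta": np.zeros((chains, keep, dims.G)),
        "alpha": np.zeros((chains, keep, dims.G, dims.T)),
        "gamma": np.zeros((chains, keep, dims.G, dims.I)),
        "kappa": np.zeros((chains, keep, dims.G, dims.K)),
        "phi": np.zeros((chains, keep, dims.A)),
        "delta": np.zeros((chains, keep, dims.A, dims.T)),
    }
    for key in sampler.tau_keys:
        store[key] = np.zeros((chains, keep))

    child_seeds = np.random.SeedSequence(seed).spawn(chains)
    acceptance: dict[str, float] = {}

    for c in range(chains):
        rng = np.random.default_rng(child_seeds[c])
        eff = EffectSet.zeros(dims)
        total_d = dataset.deaths.sum(axis=(1, 2, 3)).astype(float)
        total_n = dataset.population.sum(axis=(1, 2, 3))
        eff.beta = np.log(np.maximum(total_d, 0.5) / total_n)
        taus = {k: float(init_tau) for k in sampler.tau_keys}
        steps = {k: 0.5 for k in sampler.tau_keys}
        log_mu = sampler.log_mu(eff)
        if not np.isfinite(sampler.loglik(log_mu)):
            raise InferenceError(
                "non-finite log-likelihood at initialization; check offsets and counts"
            )
        for b in sampler.blocks:
            b.accepted = b.proposed = 0

        for it in range(iterations):
            in_warmup = it < warmup
            for b in sampler.blocks:
                log_mu = sampler.update_block(b, eff, log_mu, taus, rng)
            sampler.update_taus(eff, taus, steps, rng, adapt=in_warmup, it=it + 1)
            if it == warmup - 1:
                for b in sampler.blocks:
                    if b.proposed > 0 and b.accepted == 0:
                        raise InferenceError(
                            f"adaptation failure: no accepted proposals for block {b.name} "
                            f"during warmup"
                        )
            if not in_warmup:
                j = it - warmup
                store["beta"][c, j] = eff.beta
                store["alpha"][c, j] = eff.alpha
                store["gamma"][c, j] = eff.gamma
                store["kappa"][c, j] = eff.kappa
                store["phi"][c, j] = eff.phi
                store["delta"][c, j] = eff.delta
                for key in sampler.tau_keys:
                    store[key][c, j] = taus[key]
        for b in sampler.blocks:
            acceptance[f"chain{c}:{b.name}"] = b.accepted / max(b.proposed, 1)

    return PosteriorResult(
        samples=store,
        spec=spec,
        seed=seed,
        chains=chains,
        iterations=iterations,
        warmup=warmup,
        acceptance=acceptance,
    )
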