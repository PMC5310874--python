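"""Structural ingredients of the spatial gender-age-period-cohort model.

The log rate in cell (g, a, i, t) is additive,

    log r_gait = beta_g + alpha_tg + gamma_ig + kappa_kg + phi_a + delta_at,

with the cohort index k = M (I - i) + t linking the age and period axes to
birth cohorts.  Each random effect carries an intrinsic Gaussian Markov
random field prior defined by a sparse precision *structure* matrix:
random walks of order 1 or 2 for the period, age and cohort effects, the
intrinsic CAR (Besag) structure Q = D - W for the spatial effect, and a
Knorr-Held Kronecker-product structure (types I-IV) for the space-time
interaction.  Sum-to-zero constraints identify the levels of the improper
fields against the gender intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.linalg
import yaml

from .data_model import AdjacencyGraph, MortalityDataset, StudyDimensions
from .errors import GapcError, StructureError
from .priors import PriorConfig

__all__ = [
    "StructureMatrix",
    "ModelSpec",
    "EffectSet",
    "ConstraintSystem",
    "cohort_index",
    "cohort_index_grid",
    "rw_precision",
    "icar_precision",
    "interaction_precision",
    "constraint_set",
    "delta_constraint_matrix",
    "linear_predictor",
]

# relative eigenvalue threshold separating the numerical kernel
_KERNEL_RTOL = 1e-8

INTERACTION_TYPES = ("none", "I", "II", "III", "IV")
RANDOM_EFFECTS = ("alpha", "gamma", "kappa", "phi", "delta")


@dataclass
class StructureMatrix:
    """Symmetric positive semidefinite precision structure with known rank."""

    matrix: np.ndarray
    rank: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise StructureError("structure matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise StructureError("structure matrix must be symmetric")

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    @property
    def null_space_basis(self) -> np.ndarray:
        """Orthonormal basis of the kernel (columns), via eigendecomposition."""
        w, v = np.linalg.eigh(self.matrix)
        thresh = _KERNEL_RTOL * max(w[-1], 1.0)
        return v[:, w < thresh]

    def numerical_rank(self) -> int:
        w = np.linalg.eigh(self.matrix)[0]
        thresh = _KERNEL_RTOL * max(w[-1], 1.0)
        return int(np.sum(w >= thresh))


def cohort_index(i: int, t: int, dims: StudyDimensions) -> int:
    """Birth-cohort index k = M (I - i) + t for 1-based age i and period t.

    i = I (oldest group) in the first period is cohort 1; i = 1 (youngest)
    in the last period is cohort K = M (I - 1) + T.
    """
    if not (1 <= i <= dims.I):
        raise GapcError(f"age index i={i} outside 1..{dims.I}")
    if not (1 <= t <= dims.T):
        raise GapcError(f"period index t={t} outside 1..{dims.T}")
    return dims.M * (dims.I - i) + t


def cohort_index_grid(dims: StudyDimensions) -> np.ndarray:
    """0-based (I, T) array mapping each cell to its cohort index."""
    i = np.arange(1, dims.I + 1)[:, None]
    t = np.arange(1, dims.T + 1)[None, :]
    return dims.M * (dims.I - i) + t - 1


def rw_precision(n: int, order: int) -> StructureMatrix:
    """Random-walk structure matrix D'D with D the order-th difference operator.

    Rank n - order; the kernel is spanned by polynomials of degree < order.
    """
    if order not in (1, 2):
        raise GapcError(f"random-walk order must be 1 or 2, got {order}")
    if n <= order:
        raise GapcError(f"need length n > order, got n={n}, order={order}")
    D = np.diff(np.eye(n), n=order, axis=0)
    return StructureMatrix(matrix=D.T @ D, rank=n - order)


def icar_precision(graph: AdjacencyGraph) -> StructureMatrix:
    """Intrinsic CAR (Besag) structure Q = D - W on the area graph.

    Row sums are zero; rank is n - c with c connected components, and the
    kernel is spanned by the component indicator vectors.
    """
    W = graph.adjacency_matrix()
    Q = np.diag(W.sum(axis=1)) - W
    return StructureMatrix(matrix=Q, rank=graph.n_nodes - graph.n_components)


def interaction_precision(
    interaction_type: str, Q_space: StructureMatrix, Q_time: StructureMatrix
) -> StructureMatrix:
    """Knorr-Held space-time interaction structure on the (a, t) grid.

    The delta vector is ordered area-major (index a*T + t).  Types:
    I unstructured x unstructured; II unstructured space x structured time;
    III structured space x unstructured time; IV structured x structured.
    Rank is the product of the factor ranks.
    """
    A, T = Q_space.size, Q_time.size
    IA = StructureMatrix(np.eye(A), A)
    IT = StructureMatrix(np.eye(T), T)
    factors = {
        "I": (IA, IT),
        "II": (IA, Q_time),
        "III": (Q_space, IT),
        "IV": (Q_space, Q_time),
    }
    if interaction_type not in factors:
        raise GapcError(f"unknown interaction type {interaction_type!r}; use I, II, III or IV")
    S, Tm = factors[interaction_type]
    return StructureMatrix(matrix=np.kron(S.matrix, Tm.matrix), rank=S.rank * Tm.rank)


@dataclass
class ConstraintSystem:
    """Linear constraints C x = 0 on a (possibly stacked) effect vector."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))

    @property
    def n_constraints(self) -> int:
        """Number of independent constraints (matrix rank)."""
        return int(np.linalg.matrix_rank(self.matrix))

    def null_basis(self) -> np.ndarray:
        """Orthonormal basis of the feasible subspace {x : Cx = 0}."""
        return scipy.linalg.null_space(self.matrix)

    def satisfied(self, x: np.ndarray, tol: float = 1e-8) -> bool:
        return bool(np.max(np.abs(self.matrix @ np.ravel(x)), initial=0.0) <= tol)


def delta_constraint_matrix(interaction_type: str, A: int, T: int) -> np.ndarray:
    """Sum-to-zero families for the interaction, matching its kernel structure.

    Type I: one overall sum; II: sum over periods within each area;
    III: sum over areas within each period; IV: both families (rank A+T-1).
    """
    n = A * T
    if interaction_type == "I":
        return np.ones((1, n))
    rows_area = np.zeros((A, n))
    for a in range(A):
        rows_area[a, a * T : (a + 1) * T] = 1.0
    rows_period = np.zeros((T, n))
    for t in range(T):
        rows_period[t, t::T] = 1.0
    if interaction_type == "II":
        return rows_area
    if interaction_type == "III":
        return rows_period
    if interaction_type == "IV":
        return np.vstack([rows_area, rows_period])
    raise GapcError(f"unknown interaction type {interaction_type!r}")


@dataclass
class ModelSpec:
    """Which effects enter the model and with what priors.

    ``rw_order`` gives the random-walk order (1 or 2) of the period, age
    and cohort effects; the Knorr-Held interaction's temporal factor is
    always a first-order walk.  ``effects`` lists the included random
    effects; the interaction delta is included iff ``interaction_type`` is
    not 'none'.  The spatial effect phi and the interaction delta are
    shared across genders (they carry no gender subscript); alpha, gamma
    and kappa are gender-specific vectors that by default share one
    precision parameter per effect.
    """

    dims: StudyDimensions
    rw_order: dict = field(default_factory=lambda: {"alpha": 1, "gamma": 2, "kappa": 2})
    interaction_type: str = "I"
    effects: tuple = ("alpha", "gamma", "kappa", "phi")
    share_spatial_across_genders: bool = True
    shared_precision_across_genders: bool = True
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise GapcError(f"interaction_type must be one of {INTERACTION_TYPES}")
        for eff, order in self.rw_order.items():
            if eff not in ("alpha", "gamma", "kappa"):
                raise GapcError(f"rw_order given for unknown effect {eff!r}")
            if order not in (1, 2):
                raise GapcError(f"rw_order[{eff!r}] must be 1 or 2")
        unknown = set(self.effects) - {"alpha", "gamma", "kappa", "phi"}
        if unknown:
            raise GapcError(f"unknown effects {unknown}; delta is controlled by interaction_type")
        self.effects = tuple(e for e in ("alpha", "gamma", "kappa", "phi") if e in self.effects)

    @property
    def active_effects(self) -> tuple:
        """All random effects present, including the interaction."""
        out = list(self.effects)
        if self.interaction_type != "none":
            out.append("delta")
        return tuple(out)

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "dims": {k: getattr(self.dims, k) for k in ("G", "A", "I", "T", "M")},
            "rw_order": dict(self.rw_order),
            "interaction_type": self.interaction_type,
            "effects": list(self.effects),
            "share_spatial_across_genders": self.share_spatial_across_genders,
            "shared_precision_across_genders": self.shared_precision_across_genders,
            "priors": {
                "family": self.priors.family,
                "pc_u": self.priors.pc_u,
                "pc_alpha": self.priors.pc_alpha,
                "sigma_max": self.priors.sigma_max,
                "intercept_variance": self.priors.intercept_variance,
            },
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            dims=StudyDimensions(**d["dims"]),
            rw_order=dict(d.get("rw_order", {"alpha": 1, "gamma": 2, "kappa": 2})),
            interaction_type=d.get("interaction_type", "I"),
            effects=tuple(d.get("effects", ("alpha", "gamma", "kappa", "phi"))),
            share_spatial_across_genders=d.get("share_spatial_across_genders", True),
            shared_precision_across_genders=d.get("shared_precision_across_genders", True),
            priors=PriorConfig(**d.get("priors", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def constraint_set(spec: ModelSpec) -> dict[str, ConstraintSystem]:
    """Sum-to-zero constraint system per active effect.

    alpha, gamma, kappa: one sum-to-zero row per gender on the stacked
    (G * len) vector; phi: one overall row; delta: the family matching the
    interaction type.
    """
    dims = spec.dims
    out: dict[str, ConstraintSystem] = {}
    lengths = {"alpha": dims.T, "gamma": dims.I, "kappa": dims.K}
    for eff, L in lengths.items():
        if eff in spec.effects:
            rows = np.zeros((dims.G, dims.G * L))
            for g in range(dims.G):
                rows[g, g * L : (g + 1) * L] = 1.0
            out[eff] = ConstraintSystem(rows)
    if "phi" in spec.effects:
        out["phi"] = ConstraintSystem(np.ones((1, dims.A)))
    if spec.interaction_type != "none":
        out["delta"] = ConstraintSystem(
            delta_constraint_matrix(spec.interaction_type, dims.A, dims.T)
        )
    return out


@dataclass
class EffectSet:
    """Realized values of every effect in the linear predictor.

    Shapes: beta (G,), alpha (G, T), gamma (G, I), kappa (G, K),
    phi (A,), delta (A, T).  Effects excluded from a model are simply
    zero arrays.
    """

    beta: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    kappa: np.ndarray
    phi: np.ndarray
    delta: np.ndarray

    @classmethod
    def zeros(cls, dims: StudyDimensions) -> "EffectSet":
        return cls(
            beta=np.zeros(dims.G),
            alpha=np.zeros((dims.G, dims.T)),
            gamma=np.zeros((dims.G, dims.I)),
            kappa=np.zeros((dims.G, dims.K)),
            phi=np.zeros(dims.A),
            delta=np.zeros((dims.A, dims.T)),
        )

    def validate_shapes(self, dims: StudyDimensions) -> None:
        expected = {
            "beta": (dims.G,),
            "alpha": (dims.G, dims.T),
            "gamma": (dims.G, dims.I),
            "kappa": (dims.G, dims.K),
            "phi": (dims.A,),
            "delta": (dims.A, dims.T),
        }
        for name, shape in expected.items():
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise StructureError(f"{name} has shape {arr.shape}, expected {shape}")

    def max_constraint_violation(self, spec: ModelSpec) -> float:
        """Largest absolute sum-to-zero violation over all active effects."""
        worst = 0.0
        for eff, system in constraint_set(spec).items():
            x = np.ravel(getattr(self, eff))
            worst = max(worst, float(np.max(np.abs(system.matrix @ x), initial=0.0)))
        return worst

    def copy(self) -> "EffectSet":
        return EffectSet(**{k: np.array(getattr(self, k)) for k in
                            ("beta", "alpha", "gamma", "kappa", "phi", "delta")})


def linear_predictor(
    effects: EffectSet, dataset: MortalityDataset, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble log r_gait and log mu_gait = log n_gait + log r_gait.

    Returns the pair (log_rate, log_mean), each of shape (G, A, I, T).
    """
    dims = spec.dims
    if dims.shape != dataset.dims.shape:
        raise StructureError(
            f"model dims {dims.shape} do not match dataset dims {dataset.dims.shape}"
        )
    effects.validate_shapes(dims)
    kgrid = cohort_index_grid(dims)  # (I, T), 0-based
    log_rate = (
        np.asarray(effects.beta)[:, None, None, None]
        + np.asarray(effects.alpha)[:, None, None, :]
        + np.asarray(effects.gamma)[:, None, :, None]
        + np.asarray(effects.kappa)[:, kgrid][:, None, :, :]
        + np.asarray(effects.phi)[None, :, None, None]
        + np.asarray(effects.delta)[None, :, None, :]
    )
    log_mean = np.log(dataset.population) + log_rate
    return log_rate, log_mean
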