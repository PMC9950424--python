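"""Linear velocity field and exact latent trajectories.

The disease state is a 5-vector tracked in a fixed canonical order::

    index 0  tau     CSF total tau (latent scale)
    index 1  abeta   CSF amyloid-beta 1-42 (latent scale)
    index 2  lang    language trait
    index 3  mem     memory trait
    index 4  praxis  praxis trait

The instantaneous rate of change is affine in the state,

    v(x, y) = (V + age_std * W_age + apoe4 * W_apoe) x + v0,

with a block-triangular constraint: the CSF rows (tau, abeta) have zero
coefficients on the cognitive columns, so biomarker dynamics are not driven
by cognitive status.  Because the field is affine, trajectories are computed
exactly with the matrix exponential of the augmented system

    d/dt [x; 1] = [[A, b], [0, 0]] [x; 1],

which needs no inversion of A and is therefore safe for singular systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS: tuple[str, ...] = ("tau", "abeta", "lang", "mem", "praxis")
N_STATE = len(CHANNELS)
CSF_INDICES = (0, 1)
COG_INDICES = (2, 3, 4)
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}


def sparsity_mask() -> np.ndarray:
    """Boolean 5x5 mask of the forced-zero block (CSF rows x cognitive cols)."""
    mask = np.zeros((N_STATE, N_STATE), dtype=bool)
    mask[np.ix_(CSF_INDICES, COG_INDICES)] = True
    return mask


# Pade-13 coefficients of the scaling-and-squaring matrix exponential
_PADE13 = (
    64764752532480000.0, 32382376266240000.0, 7771770303897600.0,
    1187353796428800.0, 129060195264000.0, 10559470521600.0,
    670442572800.0, 33522128640.0, 1323241920.0, 40840800.0,
    960960.0, 16380.0, 182.0, 1.0,
)
_PADE13_THETA = 5.371920351148152


def expm_batch(A: np.ndarray) -> np.ndarray:
    """Matrix exponential of a batch of small matrices (..., n, n).

    Scaling-and-squaring with a degree-13 Pade approximant, fully vectorised
    over the batch; the per-matrix squaring count follows each matrix's
    infinity norm.  Intended for the 6x6 augmented systems this package
    propagates, where batch sizes reach thousands per likelihood evaluation.
    """
    A = np.asarray(A, dtype=float)
    norms = np.abs(A).sum(axis=-1).max(axis=-1)
    with np.errstate(divide="ignore"):
        s = np.ceil(np.log2(np.maximum(norms, 1e-300) / _PADE13_THETA))
    s = np.maximum(s, 0.0)
    Asc = A / np.exp2(s)[..., None, None]
    b = _PADE13
    eye = np.eye(A.shape[-1])
    with np.errstate(over="ignore", invalid="ignore"):
        A2 = Asc @ Asc
        A4 = A2 @ A2
        A6 = A4 @ A2
        U = Asc @ (A6 @ (b[13] * A6 + b[11] * A4 + b[9] * A2)
                   + b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * eye)
        V = (A6 @ (b[12] * A6 + b[10] * A4 + b[8] * A2)
             + b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * eye)
        X = np.linalg.solve(V - U, V + U)
        s_int = s.astype(int)
        for k in range(int(s_int.max()) if s_int.size else 0):
            mask = s_int > k
            X[mask] = X[mask] @ X[mask]
    return X


def _check_state(x: np.ndarray, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != N_STATE:
        raise ValueError(f"{name} must have length {N_STATE}, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def _check_matrix(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (N_STATE, N_STATE):
        raise ValueError(f"{name} must be {N_STATE}x{N_STATE}, got {m.shape}")
    return m


@dataclass(frozen=True)
class CovariateVector:
    """Subject covariates entering the velocity field and the diagnosis model.

    age_std is baseline age standardised with the cohort constants; apoe4 is a
    binary carrier indicator for the APOE epsilon-4 allele.
    """

    age_std: float
    apoe4: int

    def __post_init__(self) -> None:
        if self.apoe4 not in (0, 1):
            raise ValueError(f"apoe4 must be 0 or 1, got {self.apoe4}")
        if not np.isfinite(self.age_std):
            raise ValueError("age_std must be finite")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.age_std, float(self.apoe4)])


@dataclass
class VelocityParams:
    """Parameters of the affine velocity field.

    V, W_age and W_apoe all carry the same forced-zero top-right block: a
    subject's CSF biomarker velocities never depend on the cognitive
    components of the state.
    """

    V: np.ndarray
    W_age: np.ndarray
    W_apoe: np.ndarray
    v0: np.ndarray
    sparsity: np.ndarray = field(default_factory=sparsity_mask)

    def __post_init__(self) -> None:
        self.V = _check_matrix(self.V, "V")
        self.W_age = _check_matrix(self.W_age, "W_age")
        self.W_apoe = _check_matrix(self.W_apoe, "W_apoe")
        self.v0 = np.asarray(self.v0, dtype=float)
        if self.v0.shape != (N_STATE,):
            raise ValueError(f"v0 must have length {N_STATE}, got {self.v0.shape}")
        for name, m in (("V", self.V), ("W_age", self.W_age), ("W_apoe", self.W_apoe)):
            if np.any(m[self.sparsity] != 0.0):
                raise ValueError(
                    f"{name} violates the CSF/cognition block constraint: "
                    "entries in rows (tau, abeta) x columns (lang, mem, praxis) must be zero"
                )

    @classmethod
    def zeros(cls) -> "VelocityParams":
        z = np.zeros((N_STATE, N_STATE))
        return cls(V=z.copy(), W_age=z.copy(), W_apoe=z.copy(), v0=np.zeros(N_STATE))

    def n_free(self) -> int:
        """Free entries: 3 matrices minus the zero block, plus the intercept."""
        per_matrix = N_STATE * N_STATE - int(self.sparsity.sum())
        return 3 * per_matrix + N_STATE


@dataclass
class AffineSystem:
    """Subject-specific affine system dx/dt = A x + b."""

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.A = _check_matrix(self.A, "A")
        self.b = np.asarray(self.b, dtype=float)
        if self.b.shape != (N_STATE,):
            raise ValueError(f"b must have length {N_STATE}, got {self.b.shape}")


def assemble_system(params: VelocityParams, y: CovariateVector) -> AffineSystem:
    """Combine population velocity parameters with subject covariates.

    A = V + age_std * W_age + apoe4 * W_apoe,  b = v0.  The forced-zero block
    is preserved because every summand carries it.
    """
    A = params.V + y.age_std * params.W_age + y.apoe4 * params.W_apoe
    return AffineSystem(A=A, b=params.v0.copy())


def velocity_at(x: np.ndarray, sys: AffineSystem) -> np.ndarray:
    """Instantaneous rate of change A x + b at state x (years^-1)."""
    x = _check_state(x)
    return x @ sys.A.T + sys.b


def affine_propagators(A: np.ndarray, b: np.ndarray, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact-flow operators for the affine ODE at each requested time.

    Returns (M, m) with leading shape broadcast from A/b batch dims and
    times, such that x(t) = M @ x0 + m.  Built from the matrix exponential of
    the augmented (6x6) system scaled by t, so singular A needs no special
    handling.  A may be batched with shape (..., 5, 5); times must then align
    with the batch shape (elementwise pairing), or A is a single matrix and
    times an arbitrary vector.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    times = np.asarray(times, dtype=float)
    if A.ndim == 2:
        aug = np.zeros((times.size, N_STATE + 1, N_STATE + 1))
        aug[:, :N_STATE, :N_STATE] = A
        aug[:, :N_STATE, N_STATE] = b
        aug *= times.reshape(-1, 1, 1)
        E = expm_batch(aug)
        M = E[:, :N_STATE, :N_STATE].reshape(times.shape + (N_STATE, N_STATE))
        m = E[:, :N_STATE, N_STATE].reshape(times.shape + (N_STATE,))
        return M, m
    # batched: one matrix per time entry
    batch = A.shape[:-2]
    if times.shape != batch:
        raise ValueError(f"batched A {A.shape} requires times of shape {batch}, got {times.shape}")
    aug = np.zeros(batch + (N_STATE + 1, N_STATE + 1))
    aug[..., :N_STATE, :N_STATE] = A
    aug[..., :N_STATE, N_STATE] = b
    aug *= times[..., None, None]
    E = expm_batch(aug)
    return E[..., :N_STATE, :N_STATE], E[..., :N_STATE, N_STATE]


def solve_trajectory(x0: np.ndarray, sys: AffineSystem, times: np.ndarray) -> np.ndarray:
    """Exact solution of dx/dt = A x + b with x(0) = x0 at the given times.

    times are in years relative to the subject's reference visit and may be
    negative (backward propagation).  Raises on numerical overflow, naming
    the offending time.
    """
    x0 = _check_state(x0, "x0")
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(times)):
        raise ValueError("times must be finite")
    M, m = affine_propagators(sys.A, sys.b, times)
    traj = M @ x0 + m
    if not np.all(np.isfinite(traj)):
        bad = times.reshape(-1)[~np.all(np.isfinite(traj.reshape(-1, N_STATE)), axis=1)]
        raise FloatingPointError(
            f"trajectory overflowed at t={bad[0]:g} years (unstable system over this horizon)"
        )
    return traj
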