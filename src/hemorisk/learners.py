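"""The four parameter learners behind one ``fit`` interface.

* **BLS** — batch least squares.  ``b^T b`` is singular by construction (five
  duplicate bias columns), so the solver returns the minimum-norm
  least-squares solution (pseudo-inverse semantics) rather than inverting the
  normal matrix literally.
* **INN** — per-sample gradient descent of the squared residual,
  ``w <- w + eta * e_k * b_k``, starting from ``w = 0``.  Samples are visited
  in label-ascending order by default, which makes its known failure mode
  visible: later near-normal samples overwrite what the extreme early ones
  taught it.
* **LSLC** — per-sample least squares under the norm-ball constraint
  ``||w||_2 <= p*||alpha||_2``.  Each sample's Lagrange multiplier has the
  scalar closed form ``lambda_k = max(0, ||b_k*y_k||/(p*||alpha||) - b_k^T
  b_k)``; an explicit projection onto the ball after every update guarantees
  feasibility at every iteration, which the raw update alone does not.
* **SCE** — shuffled complex evolution, a gradient-free population search:
  seed n*A points in a box, rank, stripe into A complexes, evolve each by
  simplex-style subcomplex steps (reflect worst point, else contract, else
  resample), reshuffle, repeat.

All learners consume a plain design matrix and label vector; ``fit`` wires
them to a TrainingSet (basis expansion + percent -> unit label scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisMatrix, build_basis
from .deep_layers import TrainingSet

#: Norm above which the INN trajectory is declared divergent.
DIVERGENCE_NORM = 1e6

ALGORITHMS = ("bls", "inn", "lslc", "sce")


@dataclass(frozen=True)
class INNConfig:
    """Per-sample gradient descent settings."""

    eta: float = 0.05
    epochs: int = 1
    sample_order: str = "label-ascending"  # or "given"

    def __post_init__(self) -> None:
        if self.eta < 0:  # a zero rate is a legal no-op
            raise ValueError(f"eta must be >= 0, got {self.eta}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.sample_order not in ("label-ascending", "given"):
            raise ValueError(f"unknown sample_order {self.sample_order!r}")


@dataclass(frozen=True)
class LSLCConfig:
    """Constrained per-sample least squares settings.

    The feasible region is the ball ||w||_2 <= p * ||alpha||_2; defaults
    (alpha = ones, p = 10) make it comfortably contain the batch solution on
    unit-scaled labels.
    """

    eta_c: float = 0.05
    alpha: np.ndarray | None = None  # defaults to ones at fit time
    p: float = 10.0

    def __post_init__(self) -> None:
        if self.eta_c <= 0:
            raise ValueError(f"eta_c must be > 0, got {self.eta_c}")
        if self.p <= 0:
            raise ValueError(f"p must be > 0, got {self.p}")
        if self.alpha is not None and np.linalg.norm(self.alpha) == 0:
            raise ValueError("alpha must have nonzero norm")


@dataclass(frozen=True)
class SCEConfig:
    """Shuffled-complex-evolution settings (population geometry + budget)."""

    n: int = 10  # points per complex
    A: int = 4  # number of complexes
    q: int = 5  # subcomplex size
    alpha_sce: int = 3  # evolutions per subcomplex
    beta_sce: int = 5  # evolution steps per complex
    Omega: int = 100  # shuffling iterations
    f_q: float = 0.0  # objective convergence target
    bounds: tuple[float, float] = (-10.0, 10.0)  # per-parameter box
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.q <= self.n:
            raise ValueError(f"need 2 <= q <= n, got q={self.q}, n={self.n}")
        if self.A < 1 or self.Omega < 1:
            raise ValueError("A and Omega must be >= 1")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError(f"bounds low < high required, got {self.bounds}")


@dataclass
class FitResult:
    """Learned weights plus the per-iteration objective trace and diagnostics."""

    w: np.ndarray
    error_trace: np.ndarray
    algorithm: str
    converged: bool = True
    seed_used: int | None = None
    n_obj_evals: int = 0
    w_norm_trace: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "w": self.w.tolist(),
            "error_trace": np.asarray(self.error_trace).tolist(),
            "converged": bool(self.converged),
            "seed": self.seed_used,
        }


def _sq_error(b: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    r = y - b @ w
    return float(r @ r)


def fit_bls(b: BasisMatrix, y: np.ndarray) -> FitResult:
    """Batch least squares: minimum-norm solution of min ||y - b w||^2."""
    y = np.asarray(y, dtype=float)
    if b.m == 0:
        raise ValueError("empty data")
    if y.shape != (b.m,):
        raise ValueError("label vector length must match basis rows")
    w, *_ = np.linalg.lstsq(b.b, y, rcond=None)
    return FitResult(
        w=w, error_trace=np.array([_sq_error(b.b, y, w)]), algorithm="bls"
    )


def fit_inn(b: BasisMatrix, y: np.ndarray, c: INNConfig = INNConfig()) -> FitResult:
    """Per-sample squared-error descent, w <- w + eta * e_k * b_k, from w = 0.

    Divergence (||w|| exceeding 1e6) stops the pass and flags the result
    non-converged rather than raising.
    """
    y = np.asarray(y, dtype=float)
    if b.m == 0:
        raise ValueError("empty data")
    B = b.b
    order = np.argsort(y, kind="stable") if c.sample_order == "label-ascending" \
        else np.arange(b.m)
    w = np.zeros(B.shape[1])
    trace = []
    converged = True
    for _ in range(c.epochs):
        for k in order:
            e_k = y[k] - B[k] @ w
            w = w + c.eta * e_k * B[k]
            if np.linalg.norm(w) > DIVERGENCE_NORM:
                converged = False
                break
        trace.append(_sq_error(B, y, w))
        if not converged:
            break
    return FitResult(
        w=w, error_trace=np.array(trace), algorithm="inn", converged=converged
    )


def fit_lslc(b: BasisMatrix, y: np.ndarray, c: LSLCConfig = LSLCConfig()) -> FitResult:
    """Per-sample constrained update with closed-form Lagrange multiplier.

    For each sample: lambda_k = max(0, ||b_k * y_k|| / (p*||alpha||) -
    b_k^T b_k), then w <- w + eta_c * b_k * y_k / (b_k^T b_k + lambda_k),
    followed by projection onto the ball ||w||_2 <= p*||alpha||_2.
    """
    y = np.asarray(y, dtype=float)
    if b.m == 0:
        raise ValueError("empty data")
    B = b.b
    alpha = np.ones(B.shape[1]) if c.alpha is None else np.asarray(c.alpha, float)
    radius = c.p * np.linalg.norm(alpha)
    if radius == 0:
        raise ValueError("p * ||alpha|| must be positive")
    w = np.zeros(B.shape[1])
    norm_trace = [0.0]
    for k in range(B.shape[0]):
        b_k = B[k]
        btb = float(b_k @ b_k)
        lam = max(0.0, np.linalg.norm(b_k * y[k]) / radius - btb)
        w = w + c.eta_c * b_k * y[k] / (btb + lam)
        nw = np.linalg.norm(w)
        if nw > radius:
            w = w * (radius / nw)
            nw = radius
        norm_trace.append(float(nw))
    return FitResult(
        w=w,
        error_trace=np.array([_sq_error(B, y, w)]),
        algorithm="lslc",
        w_norm_trace=np.array(norm_trace),
    )


def _sce_evolve_complex(
    pts: np.ndarray, vals: np.ndarray, objective, c: SCEConfig, rng, lo, hi
) -> tuple[np.ndarray, np.ndarray, int]:
    """Evolve one complex in place via subcomplex simplex steps."""
    n_evals = 0
    for _ in range(c.beta_sce):
        # rank-weighted (triangular) choice favours good points in the subcomplex
        order = np.argsort(vals)
        pts, vals = pts[order], vals[order]
        n = len(pts)
        probs = 2.0 * (n - np.arange(n)) / (n * (n + 1))
        sub = rng.choice(n, size=c.q, replace=False, p=probs)
        for _ in range(c.alpha_sce):
            sub = sub[np.argsort(vals[sub])]
            worst = sub[-1]
            centroid = pts[sub[:-1]].mean(axis=0)
            new = 2.0 * centroid - pts[worst]  # reflection
            if np.any(new < lo) or np.any(new > hi):
                new = rng.uniform(lo, hi)
            f_new = objective(new)
            n_evals += 1
            if not np.isfinite(f_new):
                new = rng.uniform(lo, hi)
                f_new = objective(new)
                n_evals += 1
            if f_new >= vals[worst]:
                new = (centroid + pts[worst]) / 2.0  # contraction
                f_new = objective(new)
                n_evals += 1
                if not np.isfinite(f_new) or f_new >= vals[worst]:
                    new = rng.uniform(lo, hi)  # random replacement
                    f_new = objective(new)
                    n_evals += 1
            if np.isfinite(f_new) and f_new < vals[worst]:
                pts[worst], vals[worst] = new, f_new
    return pts, vals, n_evals


def fit_sce(objective, dim: int, c: SCEConfig = SCEConfig()) -> FitResult:
    """Shuffled complex evolution over a box, minimizing ``objective``.

    Seeds n*A points uniformly in the box, ranks them, stripes by rank into A
    complexes, evolves each complex, reshuffles, and repeats for Omega
    iterations or until the best objective value reaches f_q.
    """
    rng = np.random.default_rng(c.seed)
    lo = np.full(dim, c.bounds[0])
    hi = np.full(dim, c.bounds[1])
    pts = rng.uniform(lo, hi, size=(c.n * c.A, dim))
    vals = np.empty(len(pts))
    n_evals = 0
    for i, p in enumerate(pts):
        v = objective(p)
        n_evals += 1
        while not np.isfinite(v):
            p = rng.uniform(lo, hi)
            v = objective(p)
            n_evals += 1
        pts[i], vals[i] = p, v

    trace = []
    converged = False
    for _ in range(c.Omega):
        order = np.argsort(vals)
        pts, vals = pts[order], vals[order]
        trace.append(float(vals[0]))
        if vals[0] <= c.f_q:
            converged = True
            break
        for a in range(c.A):  # rank striping: complex a gets points a, a+A, ...
            idx = np.arange(a, len(pts), c.A)
            cp, cv, ev = _sce_evolve_complex(
                pts[idx].copy(), vals[idx].copy(), objective, c, rng, lo, hi
            )
            pts[idx], vals[idx] = cp, cv
            n_evals += ev
    best = int(np.argmin(vals))
    trace.append(float(vals[best]))
    return FitResult(
        w=pts[best],
        error_trace=np.array(trace),
        algorithm="sce",
        converged=converged or vals[best] <= c.f_q,
        seed_used=c.seed,
        n_obj_evals=n_evals,
    )


def fit(
    algorithm: str,
    ts: TrainingSet,
    inn: INNConfig = INNConfig(),
    lslc: LSLCConfig = LSLCConfig(),
    sce: SCEConfig = SCEConfig(),
) -> FitResult:
    """Fit one learner on a TrainingSet's train partition.

    Builds the 35-column basis from the train rows and scales labels from
    percent to [-1, 1].  SCE minimizes the squared training error over its
    bounds box.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    train = ts.partition("train") if ts.split_tag is not None else ts
    if train.m == 0:
        raise ValueError("training partition is empty")
    b = build_basis(train.d_e)
    y = train.d_tr / 100.0
    if algorithm == "bls":
        return fit_bls(b, y)
    if algorithm == "inn":
        return fit_inn(b, y, inn)
    if algorithm == "lslc":
        return fit_lslc(b, y, lslc)
    B = b.b

    def objective(w: np.ndarray) -> float:
        return _sq_error(B, y, w)

    return fit_sce(objective, dim=B.shape[1], c=sce)
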