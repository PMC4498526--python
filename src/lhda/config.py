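"""Training configuration for the hyperplane discriminant learner."""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .exceptions import ValidationError

SOLVER_MODES = ("exact", "surrogate")
INIT_MODES = ("screening", "uniform")


@dataclass(frozen=True)
class LHDAConfig:
    """Hyper-parameters of weight learning and hyperplane classification.

    Attributes
    ----------
    k : int
        Neighbors spanning each class-local hyperplane.
    lam : float
        l1 penalty strength on the weights (sparsity pressure); ``lam >= 0``.
    beta : float
        Slope of the sigmoid surrogate for the 0/1 margin-error step.
    eta : float
        Initial gradient step size; backtracking halves it as needed.
    max_iter : int
        Cap on alternation rounds (hyperplane re-estimation + gradient step).
    tol : float
        Convergence threshold on the l1 change of ``w`` between rounds.
    solver_mode : str
        ``"exact"`` solves the weighted-L1 simplex projection as a linear
        program; ``"surrogate"`` uses the linear upper bound whose optimum is
        the nearest single neighbor.
    init : str
        Starting point of the weight search.  ``"screening"`` (default)
        seeds each weight from the feature's univariate 1-NN leave-one-out
        accuracy, which places the search inside the informative basin when
        most features are noise; ``"uniform"`` starts from equal weights.
    ratio_cap : float
        Substitute margin ratio when the nearest-miss distance is zero but
        the nearest-hit distance is not.
    seed : int or None
        RNG seed; the learner itself is deterministic, this only seeds data
        generation / CV splitting done on its behalf.
    """

    k: int = 3
    lam: float = 1.0
    beta: float = 5.0
    eta: float = 0.1
    max_iter: int = 100
    tol: float = 1e-4
    solver_mode: str = "exact"
    init: str = "screening"
    ratio_cap: float = 1e6
    seed: int | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if self.lam < 0:
            raise ValidationError(f"lam must be >= 0, got {self.lam}")
        for name in ("beta", "eta", "tol", "ratio_cap"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.solver_mode not in SOLVER_MODES:
            raise ValidationError(
                f"solver_mode must be one of {SOLVER_MODES}, got {self.solver_mode!r}"
            )
        if self.init not in INIT_MODES:
            raise ValidationError(
                f"init must be one of {INIT_MODES}, got {self.init!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)
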