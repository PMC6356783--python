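"""Run configuration with the model's standard hyper-parameter defaults.

Defaults: symmetric word smoothing lam_w = 200/W, initial prior alpha = 50/T
(only an initialization — the feature regression re-estimates alpha during
inference), feature-weight prior Normal(mu=0, sigma2=1). Chain schedule for
training: one chain, 2000 sweeps with 1000 burn-in, recording every 50 sweeps
for 20 snapshots; for prediction fold-in: 1000 sweeps, 500 burn-in, record
every 50. Variational inference: up to 1000 global iterations; per-document
local loops stop at (1/Nd) sum_t |delta gamma_dt| < 1e-5 or 100 iterations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass
class TrainConfig:
    """Hyper-parameters and schedule for model training."""

    inference: str = "cgs"            # cgs | cvb | cvb0
    # Gibbs schedule
    iterations: int = 2000
    burn_in: int = 1000
    thin: int = 50
    records: int = 20
    # feature-weight optimization schedule inside the chain
    beta_interval: int = 20
    beta_burnin: int = 100
    beta_damping: float = 0.5
    # variational schedule
    global_iters: int = 1000
    local_iters: int = 100
    local_tol: float = 1e-5
    global_tol: float = 1e-6
    # model hyper-parameters
    mu: float = 0.0
    sigma2: float = 1.0
    lambda_scale: float = 200.0       # lam_w = lambda_scale / W
    alpha_init: float | None = None   # None -> 50 / T
    update_features: bool = True      # False: plain label-masked LLDA reduction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inference not in ("cgs", "cvb", "cvb0"):
            raise ValueError(f"unknown inference method {self.inference!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PredictConfig:
    """Fold-in schedule for scoring new genes under a fitted model."""

    method: str = "cgs"               # cgs | cvb0
    iterations: int = 1000
    burn_in: int = 500
    thin: int = 50
    local_iters: int = 100
    local_tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("cgs", "cvb0"):
            raise ValueError(f"unknown prediction method {self.method!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CVConfig:
    """Cross-validation driver settings: 5 folds, 5 independent rounds."""

    n_folds: int = 5
    n_rounds: int = 5
    seed: int = 0
    use_bmd: bool = False
    bmd_max_rank: int | None = None
    binarize_policy: str = "uniform"  # uniform | tuned
    train: TrainConfig = field(default_factory=TrainConfig)
    predict: PredictConfig = field(default_factory=PredictConfig)

    def to_dict(self) -> dict:
        return asdict(self)
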