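"""Registration configuration: a flat, schema-validated JSON file.

Unknown keys are rejected by name so a typo never silently falls back to a
default mid-batch.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .nonrigid import AnnealingSchedule, NonRigidConfig
from .rigid import RigidConfig

__all__ = ["RegistrationConfig"]


@dataclass
class RegistrationConfig:
    """All tunable registration parameters, flat for serialization.

    Correspondence: ``k`` nearest neighbors and the push–pull balance.
    Outliers: tolerance multiplier ``kappa`` and re-weighting iterations.
    Rigid: iteration cap, convergence tolerance (× target bbox diagonal),
    and whether isotropic scale is estimated.  Non-rigid: the annealing
    schedule (viscous/elastic Gaussian-smoothing passes, high→low) and an
    optional coverage RMS stopping threshold in mm.  ``seed`` drives only
    the permutation tests of the validation statistics.
    """

    k: int = 3
    push_pull_balance: float = 0.5
    kappa: float = 3.0
    inlier_updates: int = 10
    use_inlier_weights: bool = True
    large_triangle_factor: float = 3.0
    # rigid
    rigid_max_iterations: int = 30
    rigid_tolerance_factor: float = 1e-5
    estimate_scale: bool = True
    # non-rigid
    num_iterations: int = 60
    viscous_start: int = 50
    viscous_end: int = 1
    elastic_start: int = 50
    elastic_end: int = 1
    smoothing_k: int = 10
    coverage_rms: float | None = None
    # statistics
    seed: int = 0
    n_permutations: int = 999

    @classmethod
    def from_json(cls, path: str | Path) -> "RegistrationConfig":
        data = json.loads(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config must be a flat JSON object")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    def rigid(self) -> RigidConfig:
        return RigidConfig(
            k=self.k,
            push_pull_balance=self.push_pull_balance,
            kappa=self.kappa,
            inlier_updates=self.inlier_updates,
            max_iterations=self.rigid_max_iterations,
            tolerance_factor=self.rigid_tolerance_factor,
            estimate_scale=self.estimate_scale,
            large_triangle_factor=self.large_triangle_factor,
            use_inlier_weights=self.use_inlier_weights,
        )

    def schedule(self) -> AnnealingSchedule:
        return AnnealingSchedule(
            num_iterations=self.num_iterations,
            viscous_start=self.viscous_start,
            viscous_end=self.viscous_end,
            elastic_start=self.elastic_start,
            elastic_end=self.elastic_end,
            smoothing_k=self.smoothing_k,
        )

    def nonrigid(self) -> NonRigidConfig:
        return NonRigidConfig(
            k=self.k,
            push_pull_balance=self.push_pull_balance,
            kappa=self.kappa,
            inlier_updates=self.inlier_updates,
            coverage_rms=self.coverage_rms,
            large_triangle_factor=self.large_triangle_factor,
            use_inlier_weights=self.use_inlier_weights,
        )
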