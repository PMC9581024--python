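"""Stepped per-epoch input-sigma schedule.

The input-sigma starts high (roughly diffraction-limited blur), which
smooths the loss landscape, and is decreased on an exponential curve that
changes only at epoch boundaries — a "stepped curve" — reaching the floor
at the final epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SigmaSchedule"]


@dataclass(frozen=True)
class SigmaSchedule:
    sigma_start: float = 10.0
    sigma_floor: float = 3.2
    epochs: int = 40
    shape: str = "exponential-step"

    def __post_init__(self) -> None:
        if not self.sigma_start >= self.sigma_floor > 0:
            raise ValueError("need sigma_start >= sigma_floor > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.shape != "exponential-step":
            raise ValueError(f"unknown schedule shape {self.shape!r}")

    @classmethod
    def cep152(cls, epochs: int = 40) -> "SigmaSchedule":
        """Schedule used for the STORM centriolar-protein data: the floor of
        3.2 px corresponds to ~30 nm at that dataset's pixel scale."""
        return cls(sigma_start=10.0, sigma_floor=3.2, epochs=epochs)

    def sigma_at_epoch(self, epoch: int) -> float:
        """Piecewise-constant sigma for ``epoch``: geometric interpolation
        from ``sigma_start`` (epoch 0) down to ``sigma_floor`` (last epoch)."""
        if not 0 <= epoch < self.epochs:
            raise ValueError(f"epoch {epoch} outside [0, {self.epochs})")
        if self.epochs == 1:
            return self.sigma_start
        frac = epoch / (self.epochs - 1)
        return self.sigma_start * (self.sigma_floor / self.sigma_start) ** frac

    def values(self) -> list[float]:
        return [self.sigma_at_epoch(e) for e in range(self.epochs)]
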