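"""Synthetic designs, responses and sweep curves with known structure.

Every statistical stage of the pipeline is testable without external data:
responses on a balanced design follow the same additive main-effects model
the ANOVA fits,

    y = mu + a_i + b_j + c_k + eps,    eps ~ Normal(0, sigma^2),

with each factor's five level offsets constrained to sum to zero
(identifiability), and sweep curves follow the exponential-decay shape the
radius sweep exhibits,

    dP(r) = p_inf + amplitude * exp(-r / decay) + eps.

All randomness comes from ``numpy.random.default_rng(seed)`` (PCG64), so a
given seed reproduces outputs bit-identically across runs and platforms.
No interactions are generated: the analysis model and the generator share
the additive structure deliberately, so generator offsets are exactly the
estimands of the ANOVA stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .doe import Design
from .sweep import SweepConfig, SweepCurve


@dataclass(frozen=True)
class EffectSpec:
    """Additive main-effects response model on a balanced design.

    Parameters
    ----------
    grand_mean : float
        Overall mean response, mmHg.
    main_effects : dict[str, tuple]
        Per factor name, 5 level offsets (mmHg) summing to zero. Factors
        omitted from the dict contribute no effect.
    noise_sd : float
        Gaussian noise standard deviation, mmHg.
    seed : int
        Generator seed.
    """

    grand_mean: float
    main_effects: dict[str, tuple[float, ...]]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, offsets in self.main_effects.items():
            if len(offsets) != 5:
                raise ValueError(f"{name}: need 5 offsets, got {len(offsets)}")
            if abs(sum(offsets)) > 1e-9:
                raise ValueError(
                    f"{name}: offsets must sum to 0, got sum {sum(offsets)}"
                )

    def to_sidecar(self, path) -> None:
        """Record spec and seed as a JSON provenance sidecar."""
        payload = {
            "grand_mean": self.grand_mean,
            "main_effects": {k: list(v) for k, v in self.main_effects.items()},
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def generate_response(design: Design, spec: EffectSpec) -> np.ndarray:
    """Draw one response vector from the additive model on the design."""
    y = np.full(design.n_runs, float(spec.grand_mean))
    for factor in design.factors:
        offsets = spec.main_effects.get(factor.name)
        if offsets is None:
            continue
        y += np.asarray(offsets, dtype=float)[design.level_index(factor.name)]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=design.n_runs)
    return y


def generate_sweep_curve(
    p_inf: float,
    amplitude: float,
    decay: float,
    noise_sd: float,
    config: SweepConfig,
    seed: int = 0,
) -> SweepCurve:
    """Exponential-decay pressure-difference curve over the swept radii.

    ``dP(r) = p_inf + amplitude * exp(-r/decay) + eps`` evaluated on the
    grid of ``config``, with the plateau diagnosed at the config threshold.
    """
    if not decay > 0:
        raise ValueError(f"decay must be > 0, got {decay}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    r = config.values
    y = p_inf + amplitude * np.exp(-r / decay)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=len(r))
    curve = SweepCurve(values=r, responses=y)
    return curve.with_plateau(config.threshold)
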