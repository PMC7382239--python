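"""Simulation parameters.

The engine advances in fixed time steps; all stochastic events are
Bernoulli trials with per-step probabilities, so a probability P maps to
a physical rate of -ln(1-P)/dt for users who need real time units.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class SimulationParams:
    """All rates, probabilities and thresholds of the engine.

    Attributes
    ----------
    element_length : float
        Fixed length of one microtubule element, µm. One element is
        added per growth step and removed per shrink step.
    t_steps : int
        Number of time steps per run.
    p_spont_cat, p_rescue : float
        Per-step probabilities of the spontaneous plus-end transitions
        growing -> shrinking (catastrophe) and shrinking -> growing
        (rescue).
    p_cat : float
        Induced-catastrophe probability on a steep-angle collision
        (interaction angle >= alpha).
    p_cross : float
        Per-step severing probability of a registered crossover;
        0.005 models wild-type katanin activity, 0 the katanin mutant.
    alpha : float
        Bundling (zippering) threshold angle, degrees: collisions below
        alpha re-align the growing tip with the target.
    k_nuc : float
        Expected nucleations per step (Poisson), reflecting the diffuse
        nucleation of plant cortical arrays.
    nucleation_mode : str
        "volume" (uniform in the interior) or "surface" (uniform on the
        membrane with tangent-plane orientation).
    d_contact : float
        Contact radius, µm: a proposed tip within d_contact of a foreign
        element triggers an interaction. Must not exceed element_length.
    p_edge_cat : float
        Catastrophe probability when the tip meets the membrane too
        steeply to deflect.
    theta_edge : float
        Incidence-angle threshold, degrees; hits shallower than this are
        deflected into the membrane tangent plane.
    minus_shrink_every : int
        If > 0, static minus ends lose one element every that many steps
        (treadmilling); 0 disables it. Minus ends freed by severing
        always depolymerize one element per step.
    r_replicates : int
        Replicate count R; replicate i runs with seed + i.
    seed : int
        Base RNG seed.
    """

    element_length: float = 0.2
    t_steps: int = 10_000
    p_spont_cat: float = 0.002
    p_rescue: float = 0.01
    p_cat: float = 0.5
    p_cross: float = 0.005
    alpha: float = 40.0
    k_nuc: float = 0.5
    nucleation_mode: str = "volume"
    d_contact: float = 0.1
    p_edge_cat: float = 1.0
    theta_edge: float = 80.0
    minus_shrink_every: int = 0
    r_replicates: int = 50
    seed: int = 0

    def __post_init__(self):
        for name in ("p_spont_cat", "p_rescue", "p_cat", "p_cross",
                     "p_edge_cat"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.element_length <= 0:
            raise ValueError("element_length must be positive")
        if self.d_contact > self.element_length:
            raise ValueError("d_contact must not exceed element_length")
        if not 0.0 < self.alpha < 90.0:
            raise ValueError("alpha must lie in (0, 90) degrees")
        if self.t_steps < 0 or self.r_replicates < 1:
            raise ValueError("t_steps >= 0 and r_replicates >= 1 required")
        if self.k_nuc < 0:
            raise ValueError("k_nuc must be non-negative")
        if self.nucleation_mode not in ("volume", "surface"):
            raise ValueError("nucleation_mode must be 'volume' or 'surface'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)
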