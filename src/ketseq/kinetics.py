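"""First-order mRNA turnover kinetics driving the count simulator.

Each gene's transcript abundance M(t) obeys dM/dt = s(t) - k*M with decay
constant k = ln(2)/t_half.  Brain mRNA half-lives are roughly 2.5-3 h, so a
10 h infusion spans ~4 half-lives and abundance effectively reaches the new
steady state, while a 1 h sample catches the response mid-transition.

The synthesis rate is piecewise constant:

* infusion, t in [0, t_end]            : s = f_mod * s0
* rebound window, t in (t_end, t_end+tau_reb] : s = s0 * f_mod**(-rho)
* afterwards                           : s = s0

The rebound excursion is geometric (a fraction ``rho`` of the infusion
effect on the log scale, opposite in sign), so abundance stays positive for
any effect size and the recovery sample shows ~rho of the main effect.
Control animals are never exposed and sit at the baseline steady state
M(0) = s0/k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticGeneProfile",
    "INFUSION_END",
    "abundance_at",
    "expression_ratio_at",
]

#: End of the infusion in hours; the recovery sample is taken 24 h later.
INFUSION_END = 10.0


@dataclass
class KineticGeneProfile:
    """Ground-truth kinetic parameters for one simulated gene.

    Parameters
    ----------
    gene_id
        Gene identifier.
    s0
        Baseline synthesis rate in abundance units (FPKM-role) per hour.
    t_half
        mRNA half-life in hours (> 0).
    f_mod
        Synthesis fold-multiplier during the infusion (> 0); 1 means no
        response (null gene).
    rho
        Rebound fraction (>= 0): after the infusion, synthesis runs at
        ``s0 * f_mod**(-rho)`` for ``tau_reb`` hours.
    tau_reb
        Duration of the rebound excursion in hours.
    class_label
        One of {"induced", "suppressed", "rebound_up", "rebound_down",
        "null"}.
    region_sex_multipliers
        Optional mapping experiment -> multiplier m applied to the effect:
        the effective fold in that experiment is ``1 + m * (f_mod - 1)``.
    """

    gene_id: str
    s0: float
    t_half: float
    f_mod: float = 1.0
    rho: float = 0.0
    tau_reb: float = 30.0
    class_label: str = "null"
    region_sex_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValueError(f"t_half must be > 0, got {self.t_half}")
        if self.s0 <= 0:
            raise ValueError(f"s0 must be > 0, got {self.s0}")
        if self.f_mod <= 0:
            raise ValueError(f"f_mod must be > 0, got {self.f_mod}")
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.class_label == "null" and self.f_mod != 1.0:
            raise ValueError("null class requires f_mod == 1")

    @property
    def k(self) -> float:
        """Decay constant ln(2)/t_half in 1/h."""
        return np.log(2.0) / self.t_half

    def effective_fold(self, experiment=None) -> float:
        """Infusion fold in a given (region, sex) experiment."""
        if experiment is None:
            return self.f_mod
        m = self.region_sex_multipliers.get(experiment, 1.0)
        return 1.0 + m * (self.f_mod - 1.0)


def _relax(m0: float, target: float, k: float, dt: float) -> float:
    # Closed form of dM/dt = S - kM over dt with steady state `target`.
    return target + (m0 - target) * np.exp(-k * dt)


def abundance_at(profile: KineticGeneProfile, t, experiment=None):
    """Transcript abundance M(t) for a gene profile, in FPKM-role units.

    Solves the turnover ODE piecewise in closed form, starting from the
    baseline steady state M(0) = s0/k.  ``t`` may be a scalar or array of
    hours since infusion start; control animals use t = 0.
    """
    t_in = np.asarray(t, dtype=float)
    scalar = t_in.ndim == 0
    t = np.atleast_1d(t_in)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    k = profile.k
    f = profile.effective_fold(experiment)
    base = profile.s0 / k
    if f == 1.0:
        out = np.full_like(t, base)
        return float(out[0]) if scalar else out

    t_end = INFUSION_END
    t_reb = t_end + profile.tau_reb
    s_inf = f * base               # steady state during infusion
    s_reb = base * f ** (-profile.rho)  # steady state during rebound window

    m_end = _relax(base, s_inf, k, t_end)
    m_reb_end = _relax(m_end, s_reb, k, profile.tau_reb)

    out = np.empty_like(t, dtype=float)
    phase1 = t <= t_end
    phase2 = (t > t_end) & (t <= t_reb)
    phase3 = t > t_reb
    out[phase1] = _relax(base, s_inf, k, t[phase1])
    out[phase2] = _relax(m_end, s_reb, k, t[phase2] - t_end)
    out[phase3] = _relax(m_reb_end, base, k, t[phase3] - t_reb)
    return float(out[0]) if scalar else out


def expression_ratio_at(profile: KineticGeneProfile, t, experiment=None):
    """True abundance ratio M(t)/M(0) relative to the un-infused baseline."""
    base = profile.s0 / profile.k
    return abundance_at(profile, t, experiment) / base
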