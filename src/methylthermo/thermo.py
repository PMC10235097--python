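"""Closed-form thermodynamics of a fitted divergence distribution.

A methylome whose background divergence follows a generalized gamma law
has differential (Gibbs) entropy available in closed form:

    S = c · [ ln(θ·Γ(δ)/α) + φ(α, δ) ],   φ(α, δ) = ψ(δ)(1/α − δ) + δ

with ψ the digamma function and c a physical constant — k_B per molecule,
the gas constant R per mole, or 1 for the dimensionless entropy in nats.
The first term is the classical (partition-function) entropy ln Z; the
second, φ, is attributed to the moving parts of the molecular machine
(ν = α·δ independent activities).  The Shannon entropy in bits is
H = S / (c·ln 2); under constant internal energy the Helmholtz free
energy change is ΔF = −T·S, and between two system states
ΔΔF = T·I_m where I_m is the information gained (lost when negative).

The location μ does not enter any of these quantities: differential
entropy is invariant under translation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import constants as _const
from scipy import special

from .errors import UnitMismatchError
from .ggfamily import GGParams

Mode = Literal["per_molecule", "molar", "dimensionless"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants and the working temperature.

    Defaults are CODATA values at T = 310.15 K (human body temperature,
    also used for plant data so that energy scales are comparable across
    organisms).  ``epsilon`` is the Landauer minimum k_B·T·ln2 dissipated
    per bit erased per machine operation.
    """

    k_B: float = _const.k
    N_A: float = _const.N_A
    R: float = _const.R
    T: float = 310.15
    ln2: float = LN2

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if abs(self.R - self.k_B * self.N_A) > 1e-6 * self.R:
            raise ValueError("inconsistent constants: R must equal k_B * N_A")

    @property
    def epsilon(self) -> float:
        """Landauer bound k_B·T·ln2 per bit, J per molecule."""
        return self.k_B * self.T * self.ln2

    @property
    def epsilon_molar(self) -> float:
        """Landauer bound R·T·ln2 per bit, J·mol⁻¹."""
        return self.R * self.T * self.ln2

    def scale(self, mode: Mode) -> float:
        if mode == "per_molecule":
            return self.k_B
        if mode == "molar":
            return self.R
        if mode == "dimensionless":
            return 1.0
        raise ValueError(f"unknown mode {mode!r}")


DEFAULT_CONSTANTS = PhysicalConstants()


def phi_term(alpha: float, delta: float) -> float:
    """Moving-parts entropy term φ(α, δ) = ψ(δ)·(1/α − δ) + δ."""
    if alpha <= 0 or delta <= 0:
        raise ValueError("alpha and delta must be positive")
    return float(special.digamma(delta) * (1.0 / alpha - delta) + delta)


def entropy_decomposition(
    params: GGParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    mode: Mode = "molar",
) -> tuple[float, float]:
    """(S_classic, S_machine): c·ln(θΓ(δ)/α) and c·φ(α,δ)."""
    c = constants.scale(mode)
    a, t, d = params.alpha, params.scale, params.delta
    s_classic = c * (math.log(t) + special.gammaln(d) - math.log(a))
    s_machine = c * phi_term(a, d)
    return float(s_classic), float(s_machine)


def gibbs_entropy(
    params: GGParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    mode: Mode = "molar",
) -> float:
    """Gibbs (differential) entropy of the fitted divergence distribution.

    Dimensionless value is in nats; per_molecule multiplies by k_B
    (J·K⁻¹), molar by R (J·K⁻¹·mol⁻¹).  μ does not enter.
    """
    s_classic, s_machine = entropy_decomposition(params, constants, mode)
    return s_classic + s_machine


def shannon_entropy(params: GGParams) -> float:
    """Shannon entropy H in bits: H = log₂(θΓ(δ)/α) + φ(α,δ)/ln2."""
    return gibbs_entropy(params, DEFAULT_CONSTANTS, "dimensionless") / LN2


def helmholtz_free_energy(
    params: GGParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    mode: Mode = "molar",
) -> tuple[float, float, float]:
    """Helmholtz free-energy change ΔF = −T·S and its split.

    Returns (deltaF, F_classic, F_machine) with F_classic = −T·S_classic
    and F_machine = −T·S_machine, in J·mol⁻¹ (molar), J (per_molecule) or
    nats·K (dimensionless S times T).  The internal energy is assumed
    unchanged by the machine operations, hence ΔF = −TΔS exactly.
    """
    s_classic, s_machine = entropy_decomposition(params, constants, mode)
    T = constants.T
    return (
        -T * (s_classic + s_machine),
        -T * s_classic,
        -T * s_machine,
    )


def information_gain(
    s_group_before: Sequence[float],
    s_group_after: Sequence[float],
) -> float:
    """Information gained between two system states, in entropy units.

    I_m = mean(S_before) − mean(S_after), the grand mean over all listed
    chromosome × replicate entropies of each group.  I_m < 0 means the
    system lost information (its entropy increased).  Both groups must be
    in the same units (this function cannot check units; mixing molar and
    per-molecule values is the caller's responsibility).
    """
    before = np.asarray(s_group_before, dtype=float)
    after = np.asarray(s_group_after, dtype=float)
    if before.size == 0 or after.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(before.mean() - after.mean())


def information_gain_paired(
    s_before: pd.Series, s_after: pd.Series
) -> pd.Series:
    """Per-chromosome-paired alternative to :func:`information_gain`.

    Both series are indexed by chromosome; returns S_before − S_after per
    chromosome.  Raises on unmatched chromosomes.
    """
    if set(s_before.index) != set(s_after.index):
        raise UnitMismatchError("chromosome sets differ between groups")
    return s_before - s_after.reindex(s_before.index)


def delta_delta_F(
    im: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """ΔΔF = T·I_m: free-energy change between two system states.

    Negative exactly when information was lost.  Units are I_m's entropy
    units times kelvin (J·mol⁻¹ for molar I_m).
    """
    return constants.T * im


def energy_from_divergence(
    chi,
    theta: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    mode: Mode = "per_molecule",
):
    """Energy dissipated per machine operation, E = (χ/θ)·k_B·T.

    χ is in bits.  Under ideal (Landauer-limit) operation θ = 1/ln2, so
    one bit costs exactly ε = k_B·T·ln2 (per molecule) or R·T·ln2
    (molar).  ``mode='molar'`` multiplies by N_A.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    chi = np.asarray(chi, dtype=float)
    e = chi / theta * constants.k_B * constants.T
    if mode == "molar":
        e = e * constants.N_A
    elif mode != "per_molecule":
        raise ValueError(f"unknown mode {mode!r}")
    if e.ndim == 0:
        return float(e)
    return e


@dataclass
class ThermoState:
    """Thermodynamic summary of one (sample, chromosome) stratum."""

    sample_id: str
    chromosome: str
    params: GGParams
    S: float
    S_classic: float
    S_machine: float
    H: float
    phi: float
    deltaF: float
    F_classic: float
    F_machine: float
    mean_chi: float
    partition_Z: float
    constant_mode: Mode = "molar"
    group_label: str = ""


def thermo_state(
    params: GGParams,
    sample_id: str = "",
    chromosome: str = "",
    mean_chi: float = float("nan"),
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    mode: Mode = "molar",
    group_label: str = "",
) -> ThermoState:
    """Assemble the full thermodynamic state from fitted parameters."""
    s_classic, s_machine = entropy_decomposition(params, constants, mode)
    s = s_classic + s_machine
    h = shannon_entropy(params)
    deltaf, f_classic, f_machine = helmholtz_free_energy(params, constants, mode)
    return ThermoState(
        sample_id=sample_id,
        chromosome=chromosome,
        params=params,
        S=s,
        S_classic=s_classic,
        S_machine=s_machine,
        H=h,
        phi=phi_term(params.alpha, params.delta),
        deltaF=deltaf,
        F_classic=f_classic,
        F_machine=f_machine,
        mean_chi=mean_chi,
        partition_Z=params.partition_z,
        constant_mode=mode,
        group_label=group_label,
    )


def states_to_frame(states: Sequence[ThermoState]) -> pd.DataFrame:
    """Serialize thermodynamic states to a flat table."""
    rows = []
    for st in states:
        rows.append(
            {
                "sample": st.sample_id,
                "group": st.group_label,
                "chromosome": st.chromosome,
                "model": st.params.model_tag,
                "alpha": st.params.alpha,
                "theta": st.params.scale,
                "delta": st.params.delta,
                "mu": st.params.mu,
                "S": st.S,
                "S_classic": st.S_classic,
                "S_machine": st.S_machine,
                "H_bits": st.H,
                "deltaF": st.deltaF,
                "mean_chi": st.mean_chi,
                "partition_Z": st.partition_Z,
                "units": st.constant_mode,
            }
        )
    return pd.DataFrame(rows)
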