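"""Parameter sets and scenario configuration.

All concentrations and expression levels are in arbitrary units (a.u.);
lengths in micrometres; rates per second unless noted.  Gene maximum levels
follow the 1:100 production:degradation convention (maximum expression 100),
with the exceptions of ARF (baseline 10, maximum 300) and the TOLS2 peptide
(per-cell production:degradation ratio 1000, compensating for production in
few cells and diffusion into many).
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

HOUR = 3600.0


@dataclass
class GeometryConfig:
    """Discrete root-tip geometry.

    The default domain is 141 x 1516 grid points at dx = 2 um (282 x 3032 um),
    with row 0 at the root tip.  ``zone_scale`` proportionally shrinks the
    developmental-zone boundaries for miniature (test-scale) tissues.
    """

    dx: float = 2.0                      # um per grid point
    n_rows: int = 1516
    zone_scale: float = 1.0
    # file widths in grid columns, outside -> inside
    width_lrcap: int = 8
    width_epidermis: int = 10
    width_cortex: int = 12
    width_endodermis: int = 7
    width_pericycle: int = 5
    width_vasculature: int = 11
    n_vasc_files: int = 2                # vasculature files per side
    initial_cell_height: int = 4         # rows (8 um)
    cap_layer_height: int = 4            # rows per curved-cap cell layer
    cap_layers: int = 4
    # zone boundaries (um, before zone_scale)
    mz_end: float = 514.0
    tz_start: float = 364.0
    lrcap_mz_end: float = 314.0

    @property
    def n_cols(self) -> int:
        side = (
            self.width_lrcap + 1 + self.width_epidermis + 1 + self.width_cortex
            + 1 + self.width_endodermis + 1 + self.width_pericycle
            + self.n_vasc_files * (1 + self.width_vasculature)
        )
        return 2 * side + 1

    @property
    def cap_rows(self) -> int:
        return self.cap_layers * (self.cap_layer_height + 1)

    def scaled(self, name: str) -> float:
        """Zone boundary (um) after applying zone_scale."""
        return getattr(self, name) * self.zone_scale


@dataclass
class TransportParameters:
    """Auxin production, degradation, diffusion and carrier transport."""

    p_auxin_baseline: float = 6e-3   # a.u. s^-1 per grid point (celltypefactor 1)
    d_auxin: float = 3e-4           # s^-1
    D_cell: float = 600.0            # um^2 s^-1, intracellular
    D_wall: float = 40.0             # um^2 s^-1, apoplast
    p_PIN: float = 0.2               # um s^-1 per membrane PIN unit
    p_auxlax: float = 0.2            # um s^-1 per membrane AUX1/LAX3 unit
    eff_basal: float = 0.3           # um s^-1, basal ABCB efflux
    inf_pas: float = 2.5             # um s^-1, passive influx
    yucca4factor: float = 0.1525     # fold increase per YUCCA4 unit (100 -> 16.25x)
    auxin_ext: float = 0.03          # a.u., external auxin at the shootward boundary
    outflow_frac: float = 0.10       # epidermal/cortical boundary outflow fraction
    D_rad: float = 10.0              # um s^-1 radial (left-right) wall exchange
    pin_expression: float = 100.0    # constant cellular PIN level
    homeostasis_k: float = 0.004     # ARF-dependent extra degradation per ARFtotal unit


@dataclass
class RegulationParameters:
    """Cell-level gene expression, signalling, chromatin and peptide rates."""

    # AUX1 (auxin importer; auxin-dependent in all model settings)
    p_AUX1: float = 1.2e-2
    Km_AUX1: float = 75.0
    d_AUX1: float = 1.2e-4
    # generalized differentiation factor
    p_Diff: float = 5e-3
    d_Diff: float = 5e-5
    Th_Diff: float = 85.0
    diff_gate_threshold: float = 80.0
    # LAX3 (importer): constant 40 in the baseline model; auxin-dependent in
    # the feedback models.  In the time-integrated model expression is split
    # into an ungated vascular part and an EpiO-gated priming part.
    lax3_constant: float = 40.0
    d_LAX3: float = 1.25e-4
    p_LAX3_basal: float = 5e-3       # direct model: basal part (max 40)
    p_LAX3_auxin: float = 7.5e-3     # direct model: auxin-induced part (max +60)
    Km_LAX3: float = 20.0
    p_vasc: float = 5e-3             # epio model: general vascular part
    Km_LAX3_vasc: float = 8.0        # low Km: vascular expression is near
                                     # saturation over the root's auxin range
    p_priming: float = 7.5e-3        # epio model: EpiO-gated priming part
    Km_LAX3_priming: float = 150.0
    # YUCCA4 (auxin biosynthesis; vasculature + pericycle, EZ/DZ)
    p_YUCCA4: float = 1.25e-2
    Km_YUCCA4: float = 20.0
    Km_YUCCA4_epio: float = 150.0
    d_YUCCA4: float = 1.25e-4
    # ARF / AUX-IAA / TIR1 signalling
    bind: float = 1.0                # ARF-AUX/IAA association, per a.u. per s
    unbind: float = 5.0              # dissociation, s^-1
    pIAA: float = 1.0                # AUX/IAA production, a.u. s^-1
    d_IAAbasal: float = 1e-3         # s^-1
    dIAATIR1: float = 5e-3           # s^-1 per a.u. auxin (TIR1-mediated)
    p_ARFbasal: float = 1e-3         # baseline ARF expression (-> level 10)
    p_ARFauxin: float = 2.9e-2       # induced ARF expression (-> level 300)
    Km_ARF: float = 30.0
    d_ARF: float = 1e-4
    # EpiO chromatin integrator
    open_EpiO: float = 3e-2          # maximum opening rate, a.u. s^-1
    close_EpiO: float = 1.5e-4       # maximum closing rate, s^-1
    frac_min: float = 0.05           # minimum effective fraction of closing
    EpiO_cap: float = 100.0 / 0.975  # opening capacity; saturating-input steady state = 100
    Km_EpiO_1: float = 290.0          # signalling half-max of opening (F1)
    n_EpiO_1: float = 8.0
    Km_EpiO_2: float = 35.0          # EpiO half-max of closing inhibition (F2)
    n_EpiO_2: float = 12.0
    Km_trans: float = 32.0           # EpiO at half-maximal transcription gate (F3)
    n_trans: float = 6.0
    # TOLS2 lateral-inhibition peptide
    p_TOLS2: float = 0.125           # -> per-cell cap 1000 at d_TOLS2
    Km_TOLS2: float = 100.0          # free-ARF half-saturation
    n_TOLS2: float = 2.0
    d_TOLS2: float = 1.25e-4
    D_TOLS2: float = 5e-4            # cell-to-cell exchange rate, s^-1 per pair
    p_IAA_TOLS2: float = 10.0        # maximum fold elevation of IAA production
    Km_IAA_1: float = 30.0            # TOLS2 half-saturation of IAA upregulation
    Km_IAA_2: float = 100.0          # free-ARF half-saturation of its repression


@dataclass
class GrowthParameters:
    """Growth, division and differentiation timing."""

    cellcycle: float = 9.0 * HOUR        # division cell cycle (s)
    expansion_duration: float = 7.0 * HOUR  # EZ doubling timescale (s)
    tz_growth_rate: Optional[float] = None  # per-um rate; None -> MZ rate
    noise_amplitude: float = 0.05        # deterministic +/-5% staggering

    @property
    def mz_rate(self) -> float:
        """Per-micrometre exponential growth rate in the meristem (s^-1)."""
        return math.log(2.0) / self.cellcycle

    @property
    def ez_rate(self) -> float:
        return math.log(2.0) / self.expansion_duration


@dataclass
class ParameterSet:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    transport: TransportParameters = field(default_factory=TransportParameters)
    regulation: RegulationParameters = field(default_factory=RegulationParameters)
    growth: GrowthParameters = field(default_factory=GrowthParameters)


@dataclass
class PulseConfig:
    """Superimposed auxin elevation (growth-off experiments)."""

    amplitude: float = 0.0       # a.u.; cell auxin is held at >= amplitude
    duration: float = 0.0        # s
    start: float = 0.0           # s, simulation time of pulse onset
    region_lo: float = 0.0       # um, lower boundary distance of target cells
    region_hi: float = 0.0       # um


@dataclass
class ScenarioConfig:
    """A ParameterSet plus experiment toggles."""

    params: ParameterSet = field(default_factory=ParameterSet)
    feedback_mode: str = "none"          # none | direct | epio
    tols2_enabled: bool = False
    aux1_asymmetry: float = 0.0          # fractional AUX1 reduction on one side
    aux1_asymmetry_side: int = 1         # +1 right, -1 left
    growth_enabled: bool = True
    radial_mode: str = "walls-only"      # off | walls-only | walls+cells | enhanced
    dz_pin_variant: str = "default"      # default | apolar-equal
    auxin_content_scale: float = 1.0
    boundary_influx_scale: float = 1.0
    arf_max_scale: float = 1.0
    homeostasis_enabled: bool = False
    epio_block_ez_start: bool = False    # disable chromatin opening in early EZ
    epio_block_window: float = 100.0     # um beyond EZ start (before zone_scale)
    pulse: PulseConfig = field(default_factory=PulseConfig)
    duration: float = 24.0 * HOUR        # s
    dt: float = 0.4                      # s
    sampling_interval: float = 100.0     # s
    burn_in: float = 0.0                 # s before sampling starts

    def validate(self) -> None:
        if self.feedback_mode not in ("none", "direct", "epio"):
            raise ValueError(f"unknown feedback_mode {self.feedback_mode!r}")
        if self.radial_mode not in ("off", "walls-only", "walls+cells", "enhanced"):
            raise ValueError(f"unknown radial_mode {self.radial_mode!r}")
        if self.dz_pin_variant not in ("default", "apolar-equal"):
            raise ValueError(f"unknown dz_pin_variant {self.dz_pin_variant!r}")
        for name in ("auxin_content_scale", "boundary_influx_scale", "arf_max_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt <= 0 or self.duration < 0:
            raise ValueError("dt must be > 0 and duration >= 0")
        if self.pulse.amplitude > 0 and self.growth_enabled and self.pulse.region_hi <= 0:
            raise ValueError("a pulse requires growth disabled or an explicit region")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        p = d.pop("params", {})
        params = ParameterSet(
            geometry=GeometryConfig(**p.get("geometry", {})),
            transport=TransportParameters(**p.get("transport", {})),
            regulation=RegulationParameters(**p.get("regulation", {})),
            growth=GrowthParameters(**p.get("growth", {})),
        )
        pulse = PulseConfig(**d.pop("pulse", {}))
        return cls(params=params, pulse=pulse, **d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
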