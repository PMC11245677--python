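"""Species-specific clock parameters from gene structure and nuclear geometry.

The delayed-autorepression oscillator that times somite segmentation is
parameterised here for a given species from three measurable quantities:

* the clock gene's structure (primary transcript length, coding length and
  intron lengths, in nucleotides), which sets the transcription and
  translation delays at fixed polymerase/ribosome speeds;
* the nuclear radius (µm), which sets both the critical repressor molecule
  count ``p_crit`` (the number of molecules realising a fixed nuclear
  concentration) and, through the export simulations in
  :mod:`segclock.nuclear_export`, the mRNA nuclear-export delay;
* the species' observed clock period, of which intron splicing occupies a
  roughly constant ~8.3% fraction.

All delays are carried in minutes internally; rates given in nt/s are
converted at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = [
    "AVOGADRO",
    "LITERS_PER_CUBIC_MICRON",
    "GeneModel",
    "NuclearGeometry",
    "DelayBreakdown",
    "ClockParameters",
    "SpeciesConfig",
    "critical_threshold",
    "translation_delay",
    "transcription_delay",
    "splicing_delay",
    "assemble_parameters",
    "round_reported",
    "species_parameter_table",
    "XENOPUS_LAEVIS",
    "AMBYSTOMA_MEXICANUM",
    "BUILTIN_SPECIES",
]

#: CODATA value, fixed so molecule-count arithmetic is reproducible.
AVOGADRO = 6.02214076e23
#: 1 µm³ = 1e-15 L.
LITERS_PER_CUBIC_MICRON = 1e-15

_LN2 = math.log(2.0)


def round_reported(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at reporting precision.

    Goes through a 9-digit decimal first so rational values that sit exactly
    on a .xx5 boundary (e.g. 783/360 = 2.175) are not pushed down by their
    binary representation.
    """
    snapped = Decimal(repr(round(float(value), 9)))
    q = Decimal(1).scaleb(-ndigits)
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of a clock gene, in nucleotides."""

    name: str
    primary_length: int
    coding_length: int
    intron_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "intron_lengths", tuple(int(x) for x in self.intron_lengths))
        if self.primary_length <= 0 or self.coding_length <= 0:
            raise DomainError(f"gene lengths must be positive: {self}")
        if any(l <= 0 for l in self.intron_lengths):
            raise DomainError(f"intron lengths must be positive: {self.intron_lengths}")
        if self.primary_length < self.coding_length + self.total_intron_length:
            raise DomainError(
                f"primary length {self.primary_length} nt shorter than coding "
                f"({self.coding_length}) plus introns ({self.total_intron_length})"
            )

    @property
    def total_intron_length(self) -> int:
        return sum(self.intron_lengths)


@dataclass(frozen=True)
class NuclearGeometry:
    """A spherical nucleus of the given radius (µm)."""

    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise DomainError(f"nuclear radius must be positive, got {self.radius}")

    @property
    def volume(self) -> float:
        """Nuclear volume in µm³."""
        return 4.0 / 3.0 * math.pi * self.radius**3


@dataclass(frozen=True)
class DelayBreakdown:
    """Production delays in minutes.

    ``T_m``, the mRNA production delay, is by definition the sum of
    transcription (``T_tx``), intron splicing (``T_in``) and nuclear export
    (``T_exp``); ``T_p`` is the translation delay.
    """

    T_tx: float
    T_in: float
    T_exp: float
    T_p: float

    def __post_init__(self) -> None:
        for name in ("T_tx", "T_in", "T_exp", "T_p"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative, got {getattr(self, name)}")

    @property
    def T_m(self) -> float:
        return self.T_tx + self.T_in + self.T_exp

    @property
    def total(self) -> float:
        """Total production delay T_m + T_p."""
        return self.T_m + self.T_p


@dataclass(frozen=True)
class ClockParameters:
    """Full kinetic parameter set of the delayed-autorepression oscillator.

    Units: ``a`` protein/mRNA/min, ``k`` mRNA/min/cell, half-lives in
    minutes, ``p_crit`` in molecules.  The degradation rate constants ``b``
    (protein) and ``c`` (mRNA) are derived as ln2/half-life.
    """

    a: float
    k: float
    h_p: float
    h_m: float
    p_crit: float
    delays: DelayBreakdown
    n: float = 2.0

    def __post_init__(self) -> None:
        for name in ("a", "h_p", "h_m", "p_crit"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")
        if self.k < 0:  # k = 0 is the (absorbing) no-transcription limit
            raise DomainError(f"k must be non-negative, got {self.k}")
        if self.n < 1:
            raise DomainError(f"Hill coefficient must be >= 1, got {self.n}")

    @property
    def b(self) -> float:
        """Protein degradation rate constant, min⁻¹."""
        return _LN2 / self.h_p

    @property
    def c(self) -> float:
        """mRNA degradation rate constant, min⁻¹."""
        return _LN2 / self.h_m

    @property
    def total_delay(self) -> float:
        return self.delays.total

    def with_total_delay(self, total: float) -> "ClockParameters":
        """Return a copy whose delays sum to ``total``.

        ``T_p`` is held at the species value and the mRNA-side components
        are rescaled proportionally to make up the difference; the dynamics
        depend on the delays only through ``T_m`` and ``T_p``, so the split
        is bookkeeping.  Totals below ``T_p`` are rejected.
        """
        d = self.delays
        new_m = total - d.T_p
        if new_m < 0:
            raise ConfigurationError(
                f"total delay {total} min is smaller than the translation "
                f"delay T_p = {d.T_p} min"
            )
        if d.T_m > 0:
            f = new_m / d.T_m
            new_delays = replace(d, T_tx=f * d.T_tx, T_in=f * d.T_in, T_exp=f * d.T_exp)
        else:
            new_delays = replace(d, T_exp=new_m)
        return replace(self, delays=new_delays)

    def with_updates(self, **kwargs: float) -> "ClockParameters":
        """Copy with scalar fields replaced (``a``, ``k``, ``h_p``, ...)."""
        return replace(self, **kwargs)


def critical_threshold(geometry: NuclearGeometry, concentration: float = 1e-9) -> float:
    """Molecule count realising ``concentration`` (molar) in the nucleus.

    Returns the continuous value; round at reporting.  E.g. a 4-µm nucleus
    at 1 nM holds ≈161 molecules, a 5.5-µm nucleus ≈420.
    """
    if not concentration > 0:
        raise DomainError(f"concentration must be positive, got {concentration}")
    volume_liters = geometry.volume * LITERS_PER_CUBIC_MICRON
    return concentration * volume_liters * AVOGADRO


def translation_delay(gene: GeneModel, rate_nt_per_s: float = 6.0) -> float:
    """Translation delay T_p in minutes at ``rate_nt_per_s`` over the CDS."""
    if not rate_nt_per_s > 0:
        raise DomainError(f"translation rate must be positive, got {rate_nt_per_s}")
    return gene.coding_length / rate_nt_per_s / 60.0


def transcription_delay(gene: GeneModel, rate_nt_per_s: float = 20.0) -> float:
    """Transcription delay T_tx in minutes over the primary transcript."""
    if not rate_nt_per_s > 0:
        raise DomainError(f"transcription rate must be positive, got {rate_nt_per_s}")
    return gene.primary_length / rate_nt_per_s / 60.0


def splicing_delay(clock_period: float, fraction: float = 0.083) -> float:
    """Intron-splicing delay T_in as a fixed fraction of the clock period."""
    if clock_period < 0:
        raise DomainError(f"clock period must be non-negative, got {clock_period}")
    if not 0.0 <= fraction <= 1.0:
        raise DomainError(f"splicing fraction must lie in [0, 1], got {fraction}")
    return clock_period * fraction


@dataclass(frozen=True)
class SpeciesConfig:
    """Everything needed to assemble :class:`ClockParameters` for one species.

    ``export_delay`` maps diffusion mode (``"normal"``/``"fractional"``) to
    the mRNA export delay T_exp in minutes — a fixed input here, estimated
    independently by :mod:`segclock.nuclear_export`.
    """

    name: str
    gene: GeneModel
    geometry: NuclearGeometry
    clock_period: float
    export_delay: Mapping[str, float]
    a: float = 4.5
    k: float = 33.0
    h_m: float = 3.0
    h_p: float = 15.0
    n: float = 2.0
    critical_concentration: float = 1e-9
    transcription_rate: float = 20.0
    translation_rate: float = 6.0
    splicing_fraction: float = 0.083

    _REQUIRED = ("name", "gene", "nuclear_radius_um", "clock_period_min", "export_delay_min")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SpeciesConfig":
        missing = [f for f in cls._REQUIRED if f not in data]
        if missing:
            raise ConfigurationError(
                f"species config is missing required field(s): {', '.join(missing)}"
            )
        gene_block = data["gene"]
        for f in ("name", "primary_length", "coding_length"):
            if f not in gene_block:
                raise ConfigurationError(f"gene block is missing required field: {f}")
        gene = GeneModel(
            name=gene_block["name"],
            primary_length=int(gene_block["primary_length"]),
            coding_length=int(gene_block["coding_length"]),
            intron_lengths=tuple(gene_block.get("intron_lengths", ())),
        )
        export = dict(data["export_delay_min"])
        for mode in ("normal", "fractional"):
            if mode not in export:
                raise ConfigurationError(f"export_delay_min is missing diffusion mode: {mode}")
        kwargs = {}
        for key, target in (
            ("a", "a"), ("k", "k"), ("h_m", "h_m"), ("h_p", "h_p"), ("n", "n"),
            ("critical_concentration_molar", "critical_concentration"),
            ("transcription_nt_per_s", "transcription_rate"),
            ("translation_nt_per_s", "translation_rate"),
            ("splicing_fraction", "splicing_fraction"),
        ):
            if key in data:
                kwargs[target] = float(data[key])
        return cls(
            name=data["name"],
            gene=gene,
            geometry=NuclearGeometry(float(data["nuclear_radius_um"])),
            clock_period=float(data["clock_period_min"]),
            export_delay=export,
            **kwargs,
        )


def assemble_parameters(config: SpeciesConfig, diffusion: str = "normal") -> ClockParameters:
    """Assemble the oscillator parameter set for one species and diffusion mode.

    Delay components are quantised to 0.01 min (reporting precision) before
    summing, so totals match the values carried through the analyses; the
    unrounded values are available from the individual delay functions.
    p_crit is kept continuous.
    """
    if isinstance(config, Mapping):
        config = SpeciesConfig.from_dict(config)
    if diffusion not in config.export_delay:
        raise ConfigurationError(
            f"no export delay configured for diffusion mode {diffusion!r} "
            f"(have {sorted(config.export_delay)})"
        )
    delays = DelayBreakdown(
        T_tx=round_reported(transcription_delay(config.gene, config.transcription_rate)),
        T_in=round_reported(splicing_delay(config.clock_period, config.splicing_fraction)),
        T_exp=round_reported(config.export_delay[diffusion]),
        T_p=round_reported(translation_delay(config.gene, config.translation_rate)),
    )
    return ClockParameters(
        a=config.a,
        k=config.k,
        h_p=config.h_p,
        h_m=config.h_m,
        p_crit=critical_threshold(config.geometry, config.critical_concentration),
        delays=delays,
        n=config.n,
    )


#: African clawed frog: compact genome, 4-µm PSM nuclei, ~56-min clock.
#: Clock-gene candidate hes5.7L: 1,604-nt primary transcript, 465-nt CDS,
#: introns of 166 and 113 nt.
XENOPUS_LAEVIS = SpeciesConfig(
    name="Xenopus laevis",
    gene=GeneModel("hes5.7L", primary_length=1604, coding_length=465,
                   intron_lengths=(166, 113)),
    geometry=NuclearGeometry(4.0),
    clock_period=56.0,
    export_delay={"normal": 6.39, "fractional": 8.36},
)

#: Axolotl: ~10-fold larger genome, 5.5-µm PSM nuclei, ~154-min clock.
#: Clock gene hes7: 8,272-nt primary transcript, 783-nt CDS, introns of
#: 3,017, 1,260 and 2,030 nt.
AMBYSTOMA_MEXICANUM = SpeciesConfig(
    name="Ambystoma mexicanum",
    gene=GeneModel("hes7", primary_length=8272, coding_length=783,
                   intron_lengths=(3017, 1260, 2030)),
    geometry=NuclearGeometry(5.5),
    clock_period=154.0,
    export_delay={"normal": 11.97, "fractional": 26.27},
)

BUILTIN_SPECIES: dict[str, SpeciesConfig] = {
    "xenopus_laevis": XENOPUS_LAEVIS,
    "ambystoma_mexicanum": AMBYSTOMA_MEXICANUM,
}


def species_parameter_table(configs: Sequence[SpeciesConfig] | None = None) -> pd.DataFrame:
    """Derived parameter table, one column per species (reported precision).

    Mirrors the standard presentation: p_crit, T_p, T_tx, T_in, per-mode
    T_exp and T_m, plus a provenance note saying which size axis (genome
    size, nuclear volume, neither) each parameter tracks.
    """
    if configs is None:
        configs = list(BUILTIN_SPECIES.values())
    notes = {
        "p_crit": "increasing nuclear volume",
        "T_p": "neither",
        "T_tx": "increasing genome size",
        "T_in": "neither",
        "T_exp (normal)": "increasing nuclear volume",
        "T_exp (fractional)": "increasing nuclear volume",
        "T_m (normal)": "increasing genome size and nuclear volume",
        "T_m (fractional)": "increasing genome size and nuclear volume",
    }
    rows: dict[str, dict[str, float]] = {key: {} for key in notes}
    for cfg in configs:
        rows["p_crit"][cfg.name] = round_reported(
            critical_threshold(cfg.geometry, cfg.critical_concentration), 0
        )
        for mode in ("normal", "fractional"):
            params = assemble_parameters(cfg, diffusion=mode)
            d = params.delays
            rows["T_p"][cfg.name] = d.T_p
            rows["T_tx"][cfg.name] = d.T_tx
            rows["T_in"][cfg.name] = d.T_in
            rows[f"T_exp ({mode})"][cfg.name] = d.T_exp
            rows[f"T_m ({mode})"][cfg.name] = round_reported(d.T_m)
    frame = pd.DataFrame(rows).T
    frame["captures"] = [notes[i] for i in frame.index]
    frame.index.name = "parameter"
    return frame
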