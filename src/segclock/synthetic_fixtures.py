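"""Synthetic inputs with known ground truth for every pipeline stage.

Three fixture kinds:

* gene models with configurable exon/intron structure (padding stands in
  for UTRs so the primary length can be set exactly);
* oscillatory time series — offset sinusoids with optional exponential
  damping and additive Gaussian noise — whose true period/amplitude are
  recorded, for exercising the extrema-based metrics;
* diffusion cases packaging a radius and effective diffusion coefficient
  with the analytic mean first-exit time r²/(6D) they imply.

Everything is seeded and bit-reproducible; fixtures serialise to the same
CSV/JSON formats the pipeline consumes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .nuclear_export import mfet_analytic
from .species_params import GeneModel

__all__ = ["TraceFixture", "DiffusionCase", "make_gene_model", "make_trace",
           "make_diffusion_case", "write_fixture_bundle"]


def make_gene_model(
    intron_lengths: Sequence[int],
    cds_length: int,
    primary_length: int | None = None,
    utr_padding: int = 0,
    name: str = "synthetic_gene",
) -> GeneModel:
    """Gene model with explicit structure.

    Either give ``primary_length`` directly (it must cover CDS + introns)
    or let it default to CDS + introns + ``utr_padding``.
    """
    introns = tuple(int(x) for x in intron_lengths)
    core = int(cds_length) + sum(introns)
    if primary_length is None:
        primary_length = core + int(utr_padding)
    if primary_length < core:
        raise DomainError(
            f"primary length {primary_length} cannot hold CDS+introns ({core})"
        )
    return GeneModel(
        name=name,
        primary_length=int(primary_length),
        coding_length=int(cds_length),
        intron_lengths=introns,
    )


@dataclass(frozen=True)
class TraceFixture:
    """A sampled oscillation with its generating ground truth."""

    time: np.ndarray
    values: np.ndarray
    period: float
    amplitude: float  # half peak-to-trough of the undamped envelope
    damping_rate: float  # min⁻¹, exponential envelope decay
    noise_sigma: float
    offset: float
    dt: float
    rng_seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.time, "mrna": self.values})

    @property
    def cycle_amplitude(self) -> float:
        """Min-to-max rise of one undamped cycle (twice the sine amplitude)."""
        return 2.0 * self.amplitude


def make_trace(
    period: float,
    amplitude: float,
    damping_rate: float = 0.0,
    noise_sigma: float = 0.0,
    t_span: float = 3100.0,
    dt: float = 0.02,
    offset: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> TraceFixture:
    """Offset (damped, noisy) cosine with known period.

    ``x(t) = offset + amplitude · e^(−damping_rate·t) · cos(2πt/period) + ε``
    with ε ~ N(0, noise_sigma²).  Minima sit exactly ``period`` apart.  The
    span must cover at least 10 cycles so transient-dropping protocols have
    material to work with.
    """
    if not period > 0 or not dt > 0:
        raise DomainError("period and dt must be positive")
    if t_span < 10.0 * period:
        raise DomainError(
            f"t_span {t_span} min is too short; need at least 10 periods ({10 * period})"
        )
    seed = None
    if noise_sigma > 0:
        if isinstance(rng, (int, np.integer)):
            seed = int(rng)
            rng = np.random.default_rng(seed)
        elif rng is None:
            raise DomainError("a seeded rng is required when noise_sigma > 0")
    if offset is None:
        offset = 2.0 * amplitude + 30.0
    t = np.arange(0.0, t_span + 0.5 * dt, dt)
    x = offset + amplitude * np.exp(-damping_rate * t) * np.cos(2.0 * np.pi * t / period)
    if noise_sigma > 0:
        x = x + rng.normal(0.0, noise_sigma, size=t.shape)
    return TraceFixture(
        time=t, values=x, period=float(period), amplitude=float(amplitude),
        damping_rate=float(damping_rate), noise_sigma=float(noise_sigma),
        offset=float(offset), dt=float(dt), rng_seed=seed,
    )


@dataclass(frozen=True)
class DiffusionCase:
    """Radius + diffusion coefficient with the analytic MFET they imply."""

    radius: float  # µm
    diffusion_coefficient: float  # µm²/min
    expected_mfet: float  # minutes, r²/(6D)


def make_diffusion_case(radius: float, diffusion_coefficient: float = 0.45) -> DiffusionCase:
    """Oracle case for the export simulations (centre start, normal mode)."""
    return DiffusionCase(
        radius=float(radius),
        diffusion_coefficient=float(diffusion_coefficient),
        expected_mfet=mfet_analytic(radius, diffusion_coefficient),
    )


def write_fixture_bundle(
    out_dir: str | Path,
    rng_seed: int = 0,
    trace_periods: Sequence[float] = (56.0, 154.0),
) -> Path:
    """Write a small fixture bundle (traces as CSV, manifest as JSON).

    The manifest records kind, seed and ground truth for every artefact so
    a consumer can re-verify each pipeline stage without re-deriving
    anything.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    for i, period in enumerate(trace_periods):
        fixture = make_trace(
            period=period, amplitude=25.0, noise_sigma=0.5, rng=rng_seed + i,
            t_span=max(3100.0, 12.0 * period), dt=0.05,
        )
        path = out_dir / f"trace_{period:g}min.csv"
        fixture.to_frame().to_csv(path, index=False)
        manifest.append(
            {
                "kind": "trace",
                "file": path.name,
                "seed": fixture.rng_seed,
                "ground_truth": {
                    "period": fixture.period,
                    "cycle_amplitude": fixture.cycle_amplitude,
                    "dt": fixture.dt,
                },
            }
        )
    for radius in (3.0, 4.0, 5.5):
        case = make_diffusion_case(radius)
        manifest.append({"kind": "diffusion_case", "ground_truth": asdict(case)})
    gene = make_gene_model(intron_lengths=(166, 113), cds_length=465, primary_length=1604,
                           name="hes5.7L_like")
    manifest.append(
        {
            "kind": "gene_model",
            "ground_truth": {
                "name": gene.name,
                "primary_length": gene.primary_length,
                "coding_length": gene.coding_length,
                "intron_lengths": list(gene.intron_lengths),
            },
        }
    )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
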