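"""File interchange: 16-bit TIFF images with JSON ground-truth sidecars,
tidy CSV for electrophysiology and gradients, FASTA for sequences, and YAML
specs for model curves."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .containers import (
    CurrentTrace,
    FluorescenceImage,
    GradientProfile,
    IVRecord,
    Particle,
    ParticleSet,
    SequenceRecord,
)
from .redistribution_model import BinomialCurveSpec

__all__ = [
    "write_image",
    "read_image",
    "iv_records_to_frame",
    "frame_to_iv_records",
    "write_iv_csv",
    "read_iv_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_fasta",
    "read_fasta",
    "write_gradient_csv",
    "read_gradient_csv",
    "load_curve_spec",
]


# -- images -----------------------------------------------------------------

def write_image(
    img: FluorescenceImage,
    path: str | Path,
    field: ParticleSet | None = None,
) -> None:
    """Write a 16-bit single-channel TIFF; ground truth (particle list and
    render metadata) goes to a ``.json`` sidecar next to it."""
    path = Path(path)
    data = np.clip(np.round(img.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {
        "pixel_size_um": img.pixel_size_um,
        "channel": img.channel,
        "meta": img.meta,
    }
    if field is not None:
        sidecar["particles"] = [
            {"x": p.x, "y": p.y, "area_px2": p.area, "peak": p.peak}
            for p in field.particles
        ]
        sidecar["frame"] = list(field.shape)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_image(path: str | Path) -> tuple[FluorescenceImage, ParticleSet | None]:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    sidecar_path = path.with_suffix(".json")
    field = None
    pixel_size, channel, meta = 0.1, "", {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size = sidecar.get("pixel_size_um", 0.1)
        channel = sidecar.get("channel", "")
        meta = sidecar.get("meta", {})
        if "particles" in sidecar:
            field = ParticleSet(
                particles=[
                    Particle(x=p["x"], y=p["y"], area=p["area_px2"], peak=p["peak"])
                    for p in sidecar["particles"]
                ],
                shape=tuple(sidecar["frame"]),
            )
    img = FluorescenceImage(
        data=data, pixel_size_um=pixel_size, channel=channel, meta=meta
    )
    return img, field


# -- electrophysiology ------------------------------------------------------

def iv_records_to_frame(records: list[IVRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for v, i in zip(rec.voltages_mv, rec.currents_pa_pf):
            rows.append(
                {"cell_id": rec.cell_id, "group": rec.group,
                 "voltage_mV": v, "current_pApF": i}
            )
    return pd.DataFrame(rows)


def frame_to_iv_records(df: pd.DataFrame) -> list[IVRecord]:
    records = []
    for (cell_id, group), sub in df.groupby(["cell_id", "group"], sort=False):
        sub = sub.sort_values("voltage_mV")
        records.append(
            IVRecord(
                cell_id=str(cell_id),
                group=str(group),
                voltages_mv=sub["voltage_mV"].to_numpy(),
                currents_pa_pf=sub["current_pApF"].to_numpy(),
            )
        )
    return records


def write_iv_csv(records: list[IVRecord], path: str | Path) -> None:
    iv_records_to_frame(records).to_csv(path, index=False)


def read_iv_csv(path: str | Path) -> list[IVRecord]:
    return frame_to_iv_records(pd.read_csv(path))


def write_trace_csv(trace: CurrentTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_ms": trace.time_ms, "current_pApF": trace.current_pa_pf}
    ).to_csv(path, index=False)


def read_trace_csv(path: str | Path, rate_khz: float | None = None) -> CurrentTrace:
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy()
    if rate_khz is None:
        rate_khz = 1.0 / (t[1] - t[0])
    return CurrentTrace(
        time_ms=t, current_pa_pf=df["current_pApF"].to_numpy(), rate_khz=rate_khz
    )


# -- sequences --------------------------------------------------------------

def write_fasta(seqs: list[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(rec.seq), id=rec.id, description="")
        for rec in seqs
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# -- gradients --------------------------------------------------------------

def write_gradient_csv(profile: GradientProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"fraction": np.arange(1, 16), "signal": profile.signals}
    ).to_csv(path, index=False)


def read_gradient_csv(
    path: str | Path, raft_indices: tuple[int, ...] = (3, 4, 5, 6)
) -> GradientProfile:
    df = pd.read_csv(path).sort_values("fraction")
    return GradientProfile(
        signals=df["signal"].to_numpy(), raft_indices=raft_indices
    )


# -- model specs ------------------------------------------------------------

def load_curve_spec(path: str | Path) -> BinomialCurveSpec:
    """YAML curve spec: ``term: p4|6p2q2|q4``, ``Ct``, ``grid`` (either an
    explicit list or ``{start, stop, num}``)."""
    cfg = yaml.safe_load(Path(path).read_text())
    grid_cfg = cfg["grid"]
    if isinstance(grid_cfg, dict):
        grid = np.linspace(grid_cfg["start"], grid_cfg["stop"], grid_cfg["num"])
    else:
        grid = np.asarray(grid_cfg, dtype=float)
    return BinomialCurveSpec(
        term=str(cfg["term"]), area_grid=grid, c_total=float(cfg.get("Ct", 1e5))
    )
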