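"""Photon-trace file formats and FASTA length extraction.

The canonical trace dialect is diff-able text: a CSV with header
``bin_index,donor,acceptor`` plus a JSON sidecar (``<path>.json``) carrying
the bin width, background rates, metadata and a format version tag.  An
equivalent HDF5 container (``.h5``/``.hdf5``) holds the same arrays and
attributes for large traces.  Round trips are lossless.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .simulate import PhotonTrace

__all__ = ["read_trace", "write_trace", "lengths_from_fasta", "TRACE_FORMAT_VERSION"]

TRACE_FORMAT_VERSION = "1"

_HDF5_SUFFIXES = {".h5", ".hdf5"}


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_trace(trace: PhotonTrace, path: str | Path) -> Path:
    """Write a trace to ``path`` (CSV + JSON sidecar, or HDF5 by suffix)."""
    path = Path(path)
    meta = {
        "version": TRACE_FORMAT_VERSION,
        "bin_width_ms": trace.bin_width_ms,
        "background_rate_donor": trace.background_rate_donor,
        "background_rate_acceptor": trace.background_rate_acceptor,
        "metadata": trace.metadata,
    }
    if path.suffix.lower() in _HDF5_SUFFIXES:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("donor", data=trace.donor_counts)
            f.create_dataset("acceptor", data=trace.acceptor_counts)
            f.attrs["version"] = TRACE_FORMAT_VERSION
            f.attrs["bin_width_ms"] = trace.bin_width_ms
            f.attrs["background_rate_donor"] = trace.background_rate_donor
            f.attrs["background_rate_acceptor"] = trace.background_rate_acceptor
            f.attrs["metadata_json"] = json.dumps(trace.metadata, sort_keys=True)
        return path
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["bin_index", "donor", "acceptor"])
        for i, (d, a) in enumerate(zip(trace.donor_counts, trace.acceptor_counts)):
            w.writerow([i, int(d), int(a)])
    _sidecar(path).write_text(json.dumps(meta, sort_keys=True, indent=1))
    return path


def read_trace(path: str | Path) -> PhotonTrace:
    """Read a trace written by :func:`write_trace`.

    Raises
    ------
    ValueError
        On missing columns, malformed or negative counts (with the offending
        line number), or a format-version mismatch.
    FileNotFoundError
        If the CSV or its sidecar is absent.
    """
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        import h5py

        with h5py.File(path, "r") as f:
            version = str(f.attrs.get("version", ""))
            if version != TRACE_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported trace format version {version!r} in {path}"
                )
            donor = np.asarray(f["donor"][...], dtype=np.int64)
            acceptor = np.asarray(f["acceptor"][...], dtype=np.int64)
            meta = json.loads(str(f.attrs.get("metadata_json", "{}")))
            return PhotonTrace(
                donor_counts=donor,
                acceptor_counts=acceptor,
                bin_width_ms=float(f.attrs["bin_width_ms"]),
                background_rate_donor=float(f.attrs["background_rate_donor"]),
                background_rate_acceptor=float(f.attrs["background_rate_acceptor"]),
                metadata=meta,
            )
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing trace sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    version = str(meta.get("version", ""))
    if version != TRACE_FORMAT_VERSION:
        raise ValueError(f"unsupported trace format version {version!r} in {sidecar}")
    donor: list[int] = []
    acceptor: list[int] = []
    with open(path, newline="") as f:
        reader = csv.reader(f)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != [
            "bin_index",
            "donor",
            "acceptor",
        ]:
            raise ValueError(
                f"{path}: expected header 'bin_index,donor,acceptor', got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                d, a = int(row[1]), int(row[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed count: {exc}") from exc
            if d < 0 or a < 0:
                raise ValueError(f"{path}:{lineno}: negative photon count")
            donor.append(d)
            acceptor.append(a)
    return PhotonTrace(
        donor_counts=np.asarray(donor, dtype=np.int64),
        acceptor_counts=np.asarray(acceptor, dtype=np.int64),
        bin_width_ms=float(meta["bin_width_ms"]),
        background_rate_donor=float(meta["background_rate_donor"]),
        background_rate_acceptor=float(meta["background_rate_acceptor"]),
        metadata=meta.get("metadata", {}),
    )


def lengths_from_fasta(path: str | Path) -> list[tuple[str, int]]:
    """Per-record nucleotide counts of a FASTA file (U and T both accepted).

    Only the lengths are used downstream; the sequences themselves carry no
    further information for the distance analysis.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq).strip()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        out.append((rec.id, len(seq)))
    return out
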