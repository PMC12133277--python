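"""CSV/TSV round-tripping for matrices, snapshots and simulated corpora."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import GroundTruthGRN, SimulationParams, SnapshotDataset

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_snapshot",
    "write_corpus",
    "read_corpus",
]


def read_matrix(path) -> tuple[np.ndarray, list[str] | None]:
    """Read a numeric matrix from CSV/TSV; returns (matrix, gene_names).

    A header row of gene names is auto-detected (non-numeric first row).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file")

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in first.strip().split(sep))
    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    values = df.to_numpy()
    if values.size == 0:
        raise ValueError(f"{path}: empty matrix")
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
        raise ValueError(f"{path}: non-numeric cells in columns {list(bad)}")
    names = [str(c) for c in df.columns] if has_header else None
    return values.astype(float), names


def write_matrix(matrix: np.ndarray, path, gene_names: list[str] | None = None) -> None:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or 0 in m.shape:
        raise ValueError(f"matrix must be 2-D and nonempty, got shape {m.shape}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if gene_names is not None and len(gene_names) != m.shape[1]:
        raise ValueError("gene_names length does not match matrix columns")
    cols = gene_names if gene_names is not None else [f"g{i}" for i in range(m.shape[1])]
    pd.DataFrame(m, columns=cols).to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_snapshot(path) -> tuple[np.ndarray, list[str] | None]:
    """Read a cells x genes expression snapshot (same format as matrices)."""
    return read_matrix(path)


def _time_tag(t: float) -> str:
    return f"{t:g}"


def write_corpus(corpus, out_dir, params: SimulationParams, seed: int) -> None:
    """One directory per sample: grn.csv, expr_t{time}.csv, manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (grn, data) in enumerate(corpus):
        d = out / f"sample_{i:05d}"
        d.mkdir(exist_ok=True)
        write_matrix(grn.matrix, d / "grn.csv")
        for t, snap in zip(data.times, data.snapshots):
            write_matrix(snap, d / f"expr_t{_time_tag(t)}.csv")
    manifest = {
        "n_samples": len(corpus),
        "params": asdict(params) | {"record_times": list(params.record_times)},
        "seed": seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_corpus(in_dir) -> list[tuple[GroundTruthGRN, SnapshotDataset]]:
    root = Path(in_dir)
    corpus = []
    for d in sorted(root.glob("sample_*")):
        grn = GroundTruthGRN(read_matrix(d / "grn.csv")[0])
        times, snaps = [], []
        for f in d.glob("expr_t*.csv"):
            times.append(float(f.stem.removeprefix("expr_t")))
            snaps.append(read_matrix(f)[0])
        order = np.argsort(times)
        data = SnapshotDataset(
            times=[times[i] for i in order],
            snapshots=[snaps[i] for i in order],
            grn=grn,
        )
        corpus.append((grn, data))
    if not corpus:
        raise ValueError(f"no sample_* directories under {root}")
    return corpus
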