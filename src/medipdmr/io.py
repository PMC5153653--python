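"""Readers and writers for the plain-text formats used across the pipeline.

Coordinates are 0-based half-open throughout; genomic tables are BED-like
TSV (chrom, start, end, name, score, strand, extras). Every file written by
a pipeline stage carries a provenance comment header (stage, seed, config
hash) so that outputs are traceable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

PROVENANCE_PREFIX = "# provenance:"


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(stage: str, seed=None, cfg_hash: str | None = None) -> str:
    parts = [f"stage={stage}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return f"{PROVENANCE_PREFIX} " + " ".join(parts)


def write_table(df: pd.DataFrame, path, *, stage: str, seed=None,
                cfg_hash: str | None = None, sep: str = "\t",
                index: bool = False, float_format: str = "%.10g") -> None:
    """Write a DataFrame as TSV/CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, seed, cfg_hash) + "\n")
        df.to_csv(fh, sep=sep, index=index, float_format=float_format)


def read_table(path, sep: str = "\t", **kwargs) -> pd.DataFrame:
    """Read a table written by :func:`write_table`, skipping comment lines."""
    return pd.read_csv(path, sep=sep, comment="#", **kwargs)


def write_probes_bed(probes: pd.DataFrame, path, **prov) -> None:
    out = pd.DataFrame({
        "chrom": probes["chrom"],
        "start": probes["start"],
        "end": probes["end"],
        "name": probes["probe_id"],
        "score": 0,
        "strand": ".",
        "cpg_class": probes.get("cpg_class", "intermediate"),
    })
    write_table(out, path, **prov)


def read_probes_bed(path) -> pd.DataFrame:
    df = read_table(path)
    df = df.rename(columns={"name": "probe_id"})
    return df[["probe_id", "chrom", "start", "end", "cpg_class"]]


def write_matrix(matrix: pd.DataFrame, path, **prov) -> None:
    """Probe-by-sample (or region-by-sample) matrix, index kept."""
    write_table(matrix.rename_axis(index=matrix.index.name or "id"),
                path, index=True, **prov)


def read_matrix(path) -> pd.DataFrame:
    return read_table(path, index_col=0)


def read_sample_meta(path) -> pd.DataFrame:
    meta = read_table(path, sep=",", dtype={"animal_id": str, "genotype": str})
    return meta.set_index("animal_id")


def write_sample_meta(meta: pd.DataFrame, path, **prov) -> None:
    write_table(meta.reset_index(), path, sep=",", **prov)
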