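"""Table formats and validation.

All tables are tab-separated with mandatory header rows; gene sets are
written in GMT (one set per line: name, description, member ids); reports
are JSON. Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "write_gmt",
    "read_gmt",
    "write_json",
    "validate_tables",
]

SCHEMAS: dict[str, list[str]] = {
    "markers": ["chrom", "pos_bp", "marker_id", "p"],
    "genes": ["gene_id", "chrom", "start_bp", "end_bp"],
    "snps": ["snp_id", "chrom", "pos_bp", "p"],
    "expr": [],     # probe_id index + strain columns
    "probes": ["probe_id", "gene_id", "target_class"],
    "homology": ["human_gene_id", "mouse_gene_id"],
    "gene_p": ["gene_id", "chrom", "anchor_bp", "p", "method"],
    "gene_p_human": ["gene_id", "chrom", "n_snps", "T_obs", "n_sims", "p_emp"],
}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a TSV table and check its header against the named schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    if kind in ("expr", "panel"):
        return pd.read_csv(path, sep="\t", index_col=0)
    df = pd.read_csv(path, sep="\t")
    want = SCHEMAS.get(kind)
    if want:
        missing = [c for c in want if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing} for table kind {kind!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    """Write gene sets in GMT: name <tab> description <tab> member ids."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                out[parts[0]] = (parts[1], parts[2:])
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Validation diagnostics

def _diag(path, problem, **detail):
    return {"file": str(path), "problem": problem, **detail}


def validate_tables(paths: dict[str, str | Path]) -> list[dict]:
    """Schema and sanity diagnostics for a set of input tables.

    ``paths`` maps table kind (as in ``SCHEMAS``) to a file path. Returns a
    machine-readable list of diagnostics; an empty list means clean.
    Never raises for content problems — only reports them.
    """
    diags: list[dict] = []
    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            diags.append(_diag(path, "missing file"))
            continue
        try:
            df = read_table(path, kind)
        except ValueError as e:
            diags.append(_diag(path, "bad header", message=str(e)))
            continue

        if kind in ("markers", "snps"):
            bad = df.index[(df["p"] <= 0) | (df["p"] > 1)]
            for i in bad:
                diags.append(_diag(path, "p out of (0, 1]", line=int(i) + 2, column="p"))
            id_col = "marker_id" if kind == "markers" else "snp_id"
            for i in df.index[df[id_col].duplicated()]:
                diags.append(_diag(path, "duplicate id", line=int(i) + 2, column=id_col))
            if (df["pos_bp"] < 1).any():
                diags.append(_diag(path, "position < 1 (coordinates are 1-based)", column="pos_bp"))
        elif kind == "genes":
            for i in df.index[df["end_bp"] < df["start_bp"]]:
                diags.append(_diag(path, "end < start", line=int(i) + 2, column="end_bp"))
            if (df["start_bp"] < 1).any():
                diags.append(_diag(path, "position < 1 (coordinates are 1-based)", column="start_bp"))
            for i in df.index[df["gene_id"].duplicated()]:
                diags.append(_diag(path, "duplicate id", line=int(i) + 2, column="gene_id"))
        elif kind == "probes":
            for i in df.index[df["probe_id"].duplicated()]:
                diags.append(_diag(path, "duplicate id", line=int(i) + 2, column="probe_id"))
    return diags
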