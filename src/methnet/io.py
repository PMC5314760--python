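"""Readers and writers for the standard tabular formats the pipeline consumes.

All readers are gzip-transparent (pandas handles ``.gz`` suffixes) and return
plain pandas/networkx containers; nothing here interprets the data.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

PROBE_ANNOT_COLUMNS = ["probe_id", "gene", "region", "chrom", "pos"]
SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_probes", "seg_mean"]
MAF_COLUMNS = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
GENE_COORD_COLUMNS = ["gene", "chrom", "start", "end"]


def _sep_for(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features x samples matrix (TSV or CSV, header = sample IDs)."""
    return pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")


def write_matrix(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=_sep_for(path))


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep=_sep_for(path), comment="#")
    missing = set(PROBE_ANNOT_COLUMNS) - set(annot.columns)
    if missing:
        raise ValueError(f"probe annotation missing columns: {sorted(missing)}")
    return annot


def read_segments(path: str | Path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep=_sep_for(path), comment="#")
    missing = set(SEG_COLUMNS) - set(seg.columns)
    if missing:
        raise ValueError(f"segment file missing columns: {sorted(missing)}")
    return seg


def read_maf(path: str | Path) -> pd.DataFrame:
    maf = pd.read_csv(path, sep=_sep_for(path), comment="#")
    missing = set(MAF_COLUMNS) - set(maf.columns)
    if missing:
        raise ValueError(f"MAF-like file missing columns: {sorted(missing)}")
    return maf


def read_gene_coords(path: str | Path) -> pd.DataFrame:
    coords = pd.read_csv(path, sep=_sep_for(path), comment="#")
    missing = set(GENE_COORD_COLUMNS) - set(coords.columns)
    if missing:
        raise ValueError(f"gene coordinate file missing columns: {sorted(missing)}")
    return coords


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if not {"sample_id", "group"} <= set(sheet.columns):
        raise ValueError("sample sheet needs sample_id and group columns")
    return sheet


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = [g for g in parts[2:] if g]
    return pathways


def write_gmt(pathways: Mapping[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def read_sif_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read an undirected edge list: two (or three, SIF-style) columns."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) >= 3:
                # SIF: source <tab> interaction-type <tab> target(s)
                edges.extend((parts[0], t) for t in parts[2:])
    return edges


def write_sif_edges(edges, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_localization(path: str | Path) -> dict[str, set[str]]:
    """gene -> set of localization terms; terms separated by ';' in column 2."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, _, terms = line.partition("\t")
            tset = {t.strip() for t in terms.split(";") if t.strip()}
            if tset:
                table.setdefault(gene, set()).update(tset)
    return table


def write_localization(table: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlocalization_terms\n")
        for gene in sorted(table):
            fh.write(f"{gene}\t{';'.join(sorted(table[gene]))}\n")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
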