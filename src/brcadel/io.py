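"""Plain-text readers and writers for every pipeline artifact.

All tabular artifacts are TSV with a header row; floats are written with a
fixed ``%.6g`` format so repeated runs are byte-identical.  The cohort
configuration maps 1:1 onto :class:`~brcadel.simulate.CohortConfig` via a
flat YAML file.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .containers import ExpressionMatrix, Signature
from .simulate import CohortConfig, GroundTruth

FLOAT_FORMAT = "%.6g"


# -- expression -------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_labels(labels: pd.Series, path) -> None:
    df = pd.DataFrame({"sample_id": labels.index, "label": labels.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def read_expression(path, labels_path) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    labels = read_labels(labels_path)
    return ExpressionMatrix(values=values, labels=labels)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return pd.Series(df["label"].to_numpy(), index=df["sample_id"], name="label")


# -- per-gene stats / signature ---------------------------------------------

def write_gene_stats(stats, path) -> None:
    df = stats.table.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_signature(signature: Signature, path) -> None:
    signature.to_frame().to_csv(path, sep="\t", index=False,
                                float_format=FLOAT_FORMAT)


def read_signature(path) -> Signature:
    return Signature.from_frame(pd.read_csv(path, sep="\t"))


# -- probes / BAF / FISH ----------------------------------------------------

_PROBE_COLS = ["chromosome", "start", "end", "probe_id", "log2ratio"]


def write_probes(profile: pd.DataFrame, path) -> None:
    cols = [c for c in _PROBE_COLS + ["call", "sample_id"] if c in profile.columns]
    profile[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_probes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})


def write_baf(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_baf(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})


def write_fish(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_fish(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chromosome": str})


def write_regions(regions: pd.DataFrame, path) -> None:
    regions.to_csv(path, sep="\t", index=False)


# -- gene sets / annotation -------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Standard GMT: set name, description, tab-separated gene list."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "band") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV with columns gene (or probe_id/gene_symbol) and band."""
    df = pd.read_csv(path, sep="\t")
    if "gene_symbol" in df.columns:
        df = df.rename(columns={"gene_symbol": "gene", "cytoband": "band"})
    return df


def read_cytoband(path) -> pd.DataFrame:
    """UCSC cytoBand dialect: chrom, start, end, band, stain (no header)."""
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chromosome", "start", "end", "band", "stain"],
                       dtype={"chromosome": str})


# -- config / truth ---------------------------------------------------------

def load_cohort_config(path) -> CohortConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return cohort_config_from_dict(raw)


def cohort_config_from_dict(raw: dict) -> CohortConfig:
    kwargs = dict(raw)
    if "genome" in kwargs:
        kwargs["genome"] = tuple(tuple(b) for b in kwargs["genome"])
    if "deleted_regions" in kwargs:
        kwargs["deleted_regions"] = tuple(tuple(r) for r in kwargs["deleted_regions"])
    if "tumor_fraction_range" in kwargs:
        kwargs["tumor_fraction_range"] = tuple(kwargs["tumor_fraction_range"])
    return CohortConfig(**kwargs)


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "samples": [
            {"sample_id": sid, "group": row["group"],
             "tumor_fraction": float(row["tumor_fraction"]),
             "regions": list(map(int, row["regions"]))}
            for sid, row in truth.samples.iterrows()
        ],
        "regions": [
            {"region": int(rid), **{k: (int(v) if k in ("start", "end") else v)
                                    for k, v in row.items()}}
            for rid, row in truth.regions.iterrows()
        ],
        "genes": {
            gid: int(r) for gid, r in truth.genes["region"].items() if r >= 0
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
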