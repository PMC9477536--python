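"""Readers and writers for every on-disk format.

Labels and clinical tables are TSV; omics matrices are CSV or TSV (delimiter
sniffed), genes as rows with a header of sample ids; pathway collections are
GMT; reports are JSON; simulation configs are YAML or JSON. All writers
round-trip bit-exactly for integer domains and to full float precision for
real domains.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Dict, Optional, Set

import numpy as np
import pandas as pd
import yaml

from .config import SimConfig
from .datatypes import LABEL_COLUMNS, OmicsBundle, SLLabelSet

__all__ = [
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "read_bundle",
    "write_bundle",
    "read_config",
    "write_report",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def read_labels(path, priority_source: Optional[str] = None) -> SLLabelSet:
    """Read a label TSV and resolve duplicates.

    Within a source, duplicate entries for a pair are kept once if unanimous
    and the pair is dropped entirely on any disagreement. Across sources,
    disagreements are resolved in favour of ``priority_source`` when given,
    otherwise the pair is dropped. Self-pairs are rejected with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing label columns {missing}")
    bad_rows = df[LABEL_COLUMNS[:3]].isna().any(axis=1)
    if bad_rows.any():
        line = int(df.index[bad_rows][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: malformed row at line {line}")
    try:
        df["label"] = df["label"].astype(int)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer label: {exc}") from None
    selfpair = df["gene_a"] == df["gene_b"]
    if selfpair.any():
        warnings.warn(f"{path}: rejected {int(selfpair.sum())} self-pair row(s)")
        df = df[~selfpair]
    # canonicalize orientation
    swapped = df["gene_a"] > df["gene_b"]
    df.loc[swapped, ["gene_a", "gene_b"]] = df.loc[swapped, ["gene_b", "gene_a"]].to_numpy()

    # within-source resolution
    resolved = []
    for (a, b, cancer, source), grp in df.groupby(["gene_a", "gene_b", "cancer", "source"]):
        if grp["label"].nunique() == 1:
            resolved.append({"gene_a": a, "gene_b": b, "label": int(grp["label"].iloc[0]),
                             "cancer": cancer, "source": source})
        # else: all duplicate entries removed (within-source disagreement)
    rdf = pd.DataFrame(resolved, columns=LABEL_COLUMNS)

    # cross-source resolution
    final = []
    for (a, b, cancer), grp in rdf.groupby(["gene_a", "gene_b", "cancer"]):
        if grp["label"].nunique() == 1:
            row = grp.iloc[0].to_dict()
            final.append(row)
            continue
        if priority_source is not None and (grp["source"] == priority_source).any():
            row = grp[grp["source"] == priority_source].iloc[0].to_dict()
            final.append(row)
        else:
            log.warning("dropping pair (%s, %s) with cross-source disagreement", a, b)
    return SLLabelSet(pd.DataFrame(final, columns=LABEL_COLUMNS))


def write_labels(labels: SLLabelSet, path) -> None:
    labels.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> Dict[str, Set[str]]:
    out: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name = fields[0]
            out[name] = set(f for f in fields[2:] if f)
    return out


def write_gmt(pathways: Dict[str, Set[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            members = sorted(pathways[name])
            fh.write("\t".join([name, "na"] + members) + "\n")


# ---------------------------------------------------------------------------
# matrices and clinical tables
# ---------------------------------------------------------------------------

_DOMAINS = ("counts", "cnv", "binary", "dependency", "tpm", "real")


def _sniff_sep(path: Path) -> str:
    if path.suffix.lower() == ".tsv":
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_matrix(path, value_domain: str = "real") -> pd.DataFrame:
    """Typed gene x sample matrix with domain validation.

    Domains: ``counts`` (integer >= 0), ``cnv`` ({-2..2}), ``binary`` ({0,1}),
    ``dependency``/``tpm``/``real`` (finite reals; tpm additionally >= 0).
    A domain violation is reported with the offending gene and sample.
    """
    if value_domain not in _DOMAINS:
        raise ValueError(f"unknown value domain {value_domain!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index.name = "gene"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene row {dup!r}")
    arr = df.to_numpy()
    def _offender(mask):
        i, j = np.argwhere(mask)[0]
        return f"gene {df.index[i]!r}, sample {df.columns[j]!r}"

    if value_domain in ("counts", "cnv", "binary"):
        if not np.isfinite(arr.astype(float)).all() or not np.allclose(arr.astype(float), np.round(arr.astype(float))):
            bad = ~np.isfinite(arr.astype(float)) | ~np.isclose(arr.astype(float), np.round(arr.astype(float)))
            raise ValueError(f"{path}: non-integer value at {_offender(bad)}")
        arr = arr.astype(np.int64)
        if value_domain == "counts" and (arr < 0).any():
            raise ValueError(f"{path}: negative count at {_offender(arr < 0)}")
        if value_domain == "cnv" and not np.isin(arr, [-2, -1, 0, 1, 2]).all():
            raise ValueError(f"{path}: CNV value outside -2..2 at {_offender(~np.isin(arr, [-2, -1, 0, 1, 2]))}")
        if value_domain == "binary" and not np.isin(arr, [0, 1]).all():
            raise ValueError(f"{path}: non-binary value at {_offender(~np.isin(arr, [0, 1]))}")
        return pd.DataFrame(arr, index=df.index, columns=df.columns)
    arr = arr.astype(float)
    if not np.isfinite(arr).all():
        raise ValueError(f"{path}: non-finite value at {_offender(~np.isfinite(arr))}")
    if value_domain == "tpm" and (arr < 0).any():
        raise ValueError(f"{path}: negative TPM at {_offender(arr < 0)}")
    return pd.DataFrame(arr, index=df.index, columns=df.columns)


def write_matrix(mat: pd.DataFrame, path) -> None:
    path = Path(path)
    mat.to_csv(path, sep=_sniff_sep(path))


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"survival_days", "event", "age", "sex", "race"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {sorted(missing)}")
    return df


def write_clinical(clin: pd.DataFrame, path) -> None:
    clin.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# bundle directory layout
# ---------------------------------------------------------------------------

_BUNDLE_FILES = {
    "dependency_crispr": ("dependency_crispr.csv", "dependency"),
    "dependency_rnai": ("dependency_rnai.csv", "dependency"),
    "cellline_mutations": ("cellline_mutations.csv", "binary"),
    "tumour_mutations": ("tumour_mutations.csv", "binary"),
    "tumour_cnv": ("tumour_cnv.csv", "cnv"),
    "tumour_counts": ("tumour_counts.csv", "counts"),
    "healthy_tpm": ("healthy_tpm.csv", "tpm"),
}


def write_bundle(bundle: OmicsBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, (fname, _) in _BUNDLE_FILES.items():
        write_matrix(getattr(bundle, attr), outdir / fname)
    if bundle.normal_counts is not None:
        write_matrix(bundle.normal_counts, outdir / "normal_counts.csv")
    write_clinical(bundle.clinical, outdir / "clinical.tsv")
    write_gmt(bundle.pathways, outdir / "pathways.gmt")
    meta = dict(bundle.metadata)
    if meta.get("designated_pair") is not None:
        meta["designated_pair"] = list(meta["designated_pair"])
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def read_bundle(indir) -> OmicsBundle:
    indir = Path(indir)
    kw = {attr: read_matrix(indir / fname, domain) for attr, (fname, domain) in _BUNDLE_FILES.items()}
    normal_path = indir / "normal_counts.csv"
    normal = read_matrix(normal_path, "counts") if normal_path.exists() else None
    clinical = read_clinical(indir / "clinical.tsv")
    pathways = read_gmt(indir / "pathways.gmt")
    meta_path = indir / "metadata.json"
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if metadata.get("designated_pair") is not None:
        metadata["designated_pair"] = tuple(metadata["designated_pair"])
    return OmicsBundle(clinical=clinical, pathways=pathways, normal_counts=normal,
                       metadata=metadata, **kw)


# ---------------------------------------------------------------------------
# config and reports
# ---------------------------------------------------------------------------

def read_config(path) -> SimConfig:
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    return SimConfig.from_dict(data or {})


def write_report(report: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, pd.Series):
            return obj.to_dict()
        return str(obj)

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
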