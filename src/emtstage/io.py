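"""Readers and writers for the external formats, the strict YAML config,
and the run manifest."""

from __future__ import annotations

import gzip
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import __version__
from .containers import CountMatrix, PairedSegmentsMatrix
from .scoring import GeneSetCollection


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {dirpath}")


def read_10x_mtx(dirpath) -> CountMatrix:
    """Read a 10x MTX triplet (matrix.mtx, features.tsv, barcodes.tsv).

    Gzipped or plain files are accepted.  Duplicate gene symbols are
    disambiguated by appending ``.1``, ``.2``, ...; the mapping is stored in
    ``gene_meta["original_symbol"]``.
    """
    dirpath = Path(dirpath)
    mtx_path = _find(dirpath, "matrix.mtx")
    feat_path = _find(dirpath, "features.tsv")
    bc_path = _find(dirpath, "barcodes.tsv")

    with _open_maybe_gz(mtx_path, "rb") as fh:
        X = sp.csr_matrix(scipy.io.mmread(fh))
    features = pd.read_csv(feat_path, sep="\t", header=None)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].tolist()

    symbols = features[1].tolist() if features.shape[1] > 1 else features[0].tolist()
    if X.shape != (len(symbols), len(barcodes)):
        raise ValueError(
            f"MTX shape {X.shape} does not match {len(symbols)} features "
            f"x {len(barcodes)} barcodes"
        )
    seen: dict[str, int] = {}
    unique = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            unique.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            unique.append(s)
    gene_meta = pd.DataFrame(
        {"original_symbol": symbols, "mito": [s.startswith("MT-") for s in symbols]},
        index=pd.Index(unique, name="gene"),
    )
    return CountMatrix(
        X, pd.Index(unique, name="gene"), pd.Index(barcodes, name="cell"), gene_meta
    )


def write_10x_mtx(counts: CountMatrix, dirpath) -> None:
    """Write the plain-text MTX triplet (no compression; text deliverable)."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dirpath / "matrix.mtx"), sp.coo_matrix(counts.X))
    feats = pd.DataFrame(
        {
            0: counts.genes,
            1: counts.genes,
            2: ["Gene Expression"] * counts.n_genes,
        }
    )
    feats.to_csv(dirpath / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.cells).to_csv(
        dirpath / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene...

    Duplicate set names or gene-less lines are errors; trailing empty fields
    are ignored.
    """
    sets: dict[str, list[str]] = {}
    with _open_maybe_gz(Path(path)) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            name = parts[0]
            genes = [g for g in parts[2:] if g.strip()]
            if name in sets:
                raise ValueError(f"duplicate set name {name!r} at line {ln}")
            if not genes:
                raise ValueError(f"set {name!r} at line {ln} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_weights_tsv(path) -> pd.Series:
    """TSV with columns ``gene`` and ``weight`` -> Series gene -> weight."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "weight"} <= set(df.columns):
        raise ValueError("weights table needs columns 'gene' and 'weight'")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate genes in weight table")
    return df.set_index("gene")["weight"].astype(float)


def read_survival_tsv(path) -> pd.DataFrame:
    """TSV with columns sample, time, event (0/1)."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "time", "event"}
    if not need <= set(df.columns):
        raise ValueError(f"survival table needs columns {sorted(need)}")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return df.set_index("sample")


def read_ct_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "gene", "ct"}
    if not need <= set(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(need)}")
    return df


def write_dsp_csv(segments: PairedSegmentsMatrix, path) -> None:
    """CSV with two annotation header rows (roi_id, segment) over gene rows."""
    ann = segments.annotations
    with open(path, "w") as fh:
        fh.write("roi_id," + ",".join(str(r) for r in ann["roi_id"]) + "\n")
        fh.write("segment," + ",".join(ann["segment"]) + "\n")
        segments.values.to_csv(fh, header=False)


def read_dsp_csv(path) -> PairedSegmentsMatrix:
    with open(path) as fh:
        roi_row = fh.readline().rstrip("\n").split(",")
        seg_row = fh.readline().rstrip("\n").split(",")
        if roi_row[0] != "roi_id" or seg_row[0] != "segment":
            raise ValueError("DSP CSV must start with roi_id and segment header rows")
        rois = roi_row[1:]
        segs = seg_row[1:]
        body = pd.read_csv(fh, header=None, index_col=0)
    cols = [f"{r}_{s}" for r, s in zip(rois, segs)]
    body.columns = cols
    body.index.name = "gene"
    ann = pd.DataFrame({"roi_id": rois, "segment": segs}, index=cols)
    return PairedSegmentsMatrix(body, ann)


# ---------------------------------------------------------------------------
# configuration and manifest


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters; defaults match the published
    analysis settings.  Unknown keys in a YAML file are rejected."""

    mad_libsize: float = 5.0
    mad_detected: float = 5.0
    mad_mito: float = 3.0
    min_cells: int = 6
    target_sum: float = 1e4
    n_hvg: int = 3000
    n_pcs: int = 13
    knn_k: int = 20
    resolution: float = 1.0
    marker: str = "VIM"
    bin_width: float = 1.0
    n_bins: int = 6
    de_alpha: float = 0.05
    de_min_lfc: float = 1.0
    use_raw_p: bool = False
    weight_exponent: float = 0.25
    n_perm: int = 1000
    mito_prefix: str = "MT-"
    seed: int = 0
    gene_sets: str | None = None
    weights_table: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def sha256(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    version: str = __version__
    config_hash: str = ""
    input_checksums: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def add_input(self, path) -> None:
        p = Path(path)
        h = hashlib.sha256(p.read_bytes()).hexdigest()
        self.input_checksums[str(p)] = h

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @staticmethod
    def now() -> str:
        return time.strftime("%Y-%m-%dT%H:%M:%S")
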