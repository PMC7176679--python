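"""File readers/writers and the run configuration.

Expression tables are TSV/CSV with a gene column and one column per sample;
UMI matrices are MatrixMarket triplets with gene/well sidecar TSVs (or a
dense TSV) joined to a plate-layout CSV. Gene lists are one symbol per line;
ligand-receptor pairs a two-column CSV. All writers round-trip losslessly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .types import ExpressionMatrix, PipelineThresholds, UmiCountMatrix, ZONES

#: default prefixes flagging ribosomal / mitochondrial genes
RIBO_PREFIXES = ("Rps", "Rpl", "Mrps", "Mrpl")
MITO_PREFIXES = ("mt-",)

_SAMPLE_RE = re.compile(r"^(?P<label>[A-Za-z]+[A-Za-z0-9]*?)[_\-](?P<mouse>.+)$")


def parse_sample_ids(sample_ids) -> pd.DataFrame:
    """Derive sample metadata from ids of the form ``<zone|condition>_<mouse>``.

    Labels in {c, vb, vc, vt} become zones; anything else (e.g. DT, mock)
    becomes a condition.
    """
    rows = {}
    for sid in sample_ids:
        m = _SAMPLE_RE.match(str(sid))
        if not m:
            raise ValueError(f"cannot parse sample id {sid!r} as label_mouse")
        label, mouse = m.group("label"), m.group("mouse")
        if label in ZONES:
            rows[sid] = {"zone": label, "condition": None, "mouse": mouse}
        else:
            rows[sid] = {"zone": None, "condition": label, "mouse": mouse}
    return pd.DataFrame.from_dict(rows, orient="index")


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    return df


def read_expression_table(path, unit: str,
                          sample_meta: pd.DataFrame | None = None
                          ) -> ExpressionMatrix:
    """Read a genes x samples table; metadata parsed from sample ids unless given."""
    df = _read_table(path)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    if sample_meta is None:
        sample_meta = parse_sample_ids(df.columns)
    return ExpressionMatrix(df, sample_meta, unit)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_umi_matrix(matrix_path, layout_path) -> UmiCountMatrix:
    """Read a UMI matrix (MTX + sidecars, or dense TSV) and its plate layout.

    For an MTX file ``X.mtx``, gene and well ids are read from
    ``X.genes.tsv`` and ``X.wells.tsv`` next to it.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(matrix_path)
        genes = pd.read_csv(matrix_path.with_suffix(".genes.tsv"),
                            header=None)[0].astype(str)
        wells = pd.read_csv(matrix_path.with_suffix(".wells.tsv"),
                            header=None)[0].astype(str)
        counts = pd.DataFrame(np.asarray(scipy.sparse.coo_matrix(mat).todense()),
                              index=genes, columns=wells)
    else:
        counts = _read_table(matrix_path)
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("UMI counts must be integers")
    counts = counts.astype(np.int64)
    layout = pd.read_csv(layout_path)
    layout["uid"] = layout["plate"].astype(str) + ":" + layout["well"].astype(str)
    layout = layout.set_index("uid")
    layout["is_empty"] = layout["is_empty"].astype(bool)
    missing = counts.columns.difference(layout.index)
    if len(missing):
        raise ValueError(f"wells absent from layout: {list(missing)[:5]}")
    return UmiCountMatrix(counts, layout.loc[list(counts.columns)])


def write_umi_matrix(umis: UmiCountMatrix, matrix_path, layout_path) -> None:
    matrix_path = Path(matrix_path)
    sparse = scipy.sparse.csr_matrix(umis.counts.to_numpy())
    scipy.io.mmwrite(str(matrix_path), sparse)
    pd.Series(umis.counts.index).to_csv(matrix_path.with_suffix(".genes.tsv"),
                                        index=False, header=False)
    pd.Series(umis.counts.columns).to_csv(matrix_path.with_suffix(".wells.tsv"),
                                          index=False, header=False)
    meta = umis.well_meta.reset_index(drop=True)
    meta[["plate", "well", "is_empty"]].to_csv(layout_path, index=False)


def _read_symbols(path) -> list[str]:
    with open(path) as fh:
        syms = [line.strip() for line in fh if line.strip()]
    return syms


def build_gene_annotation(genes, ligand_genes=(), receptor_genes=(),
                          matrisome_genes=(), ribo_prefixes=RIBO_PREFIXES,
                          mito_prefixes=MITO_PREFIXES) -> pd.DataFrame:
    """Boolean annotation flags per gene symbol (prefix rules for ribo/mito)."""
    genes = pd.Index(genes, dtype=str)
    return pd.DataFrame({
        "is_ribosomal": [g.startswith(tuple(ribo_prefixes)) for g in genes],
        "is_mitochondrial": [g.startswith(tuple(mito_prefixes)) for g in genes],
        "is_ligand": genes.isin(set(ligand_genes)),
        "is_receptor": genes.isin(set(receptor_genes)),
        "is_matrisome": genes.isin(set(matrisome_genes)),
    }, index=genes)


def read_gene_lists(genes, ligand_path=None, receptor_path=None,
                    matrisome_path=None, **prefix_kwargs) -> pd.DataFrame:
    """Read symbol lists and produce the annotation table for ``genes``."""
    return build_gene_annotation(
        genes,
        ligand_genes=_read_symbols(ligand_path) if ligand_path else (),
        receptor_genes=_read_symbols(receptor_path) if receptor_path else (),
        matrisome_genes=_read_symbols(matrisome_path) if matrisome_path else (),
        **prefix_kwargs,
    )


def read_lr_pairs(path) -> pd.DataFrame:
    """Two-column ligand,receptor CSV -> deduplicated pair table."""
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("pair file needs 'ligand' and 'receptor' columns")
    df = df[["ligand", "receptor"]]
    if df.isna().any().any():
        raise ValueError("empty ligand/receptor field")
    df = df.astype(str)
    if (df["ligand"].str.len() == 0).any() or \
            (df["receptor"].str.len() == 0).any():
        raise ValueError("empty ligand/receptor field")
    return df.drop_duplicates(ignore_index=True)


_RUNCONFIG_KEYS = {"inputs", "thresholds", "seed", "outdir"}


@dataclass
class RunConfig:
    """Run configuration: input paths, threshold overrides, seed, output dir."""

    inputs: dict = field(default_factory=dict)
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    seed: int = 0
    outdir: str = "villizon_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        thr = PipelineThresholds().override(**(raw.get("thresholds") or {}))
        return cls(inputs=raw.get("inputs") or {}, thresholds=thr,
                   seed=int(raw.get("seed", 0)),
                   outdir=str(raw.get("outdir", "villizon_out")))

    def as_dict(self) -> dict:
        return {"inputs": self.inputs, "thresholds": self.thresholds.as_dict(),
                "seed": self.seed, "outdir": self.outdir}
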