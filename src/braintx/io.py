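"""Plain-text readers and writers for the pipeline's tabular formats."""
from __future__ import annotations

import pandas as pd

REQUIRED_META_COLUMNS = ("subject", "region", "diagnosis", "sex", "age", "PMI", "pH", "RIN")


def read_counts(path) -> pd.DataFrame:
    """Gene x sample matrix TSV: gene ids in the first column, sample header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in counts matrix")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids in counts matrix")
    return df


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing column(s): {missing}")
    dup = meta.reset_index().duplicated(subset=["subject", "region"])
    if dup.any():
        raise ValueError("duplicate (subject, region) rows in metadata")
    return meta


def read_partner_table(path) -> pd.DataFrame:
    """External DEG table TSV with columns gene, log2FC, p."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for need in ("gene", "log2fc", "p"):
        if need not in cols:
            raise ValueError(f"partner table missing column {need!r}")
    df = df.rename(columns={cols["gene"]: "gene", cols["log2fc"]: "log2FC", cols["p"]: "p"})
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in partner table")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError("partner p-values must lie in (0, 1]")
    return df.set_index("gene")
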