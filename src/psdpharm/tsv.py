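"""Tab-separated readers and writers for all pipeline artifacts.

Dialect: UTF-8, header row, tab separator, missing encoded as empty field.
Peptide matrices are written as three files sharing a path prefix:
``<prefix>.abundance.tsv`` (rows = peptides, columns = plex.channel keys),
``<prefix>.channels.tsv`` and ``<prefix>.pep2prot.tsv`` (one row per
peptide-protein pair).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import KnockdownAtlas, PeptideMatrix, ProteinMatrix, SignedSignature
from .network import InteractionGraph

_TSV = dict(sep="\t", na_rep="")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, index=index, **_TSV)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_peptide_matrix(m: PeptideMatrix, prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    paths = [
        prefix.with_suffix(".abundance.tsv"),
        prefix.with_suffix(".channels.tsv"),
        prefix.with_suffix(".pep2prot.tsv"),
    ]
    m.abundance.rename_axis("peptide").to_csv(paths[0], **_TSV)
    m.channel_meta.rename_axis("channel_key").to_csv(paths[1], **_TSV)
    pairs = [
        {"peptide": pep, "protein": prot}
        for pep, prots in m.pep2prot.items()
        for prot in prots
    ]
    pd.DataFrame(pairs).to_csv(paths[2], index=False, **_TSV)
    return paths


def read_peptide_matrix(prefix: str | Path) -> PeptideMatrix:
    prefix = Path(prefix)
    abundance = pd.read_csv(prefix.with_suffix(".abundance.tsv"), sep="\t", index_col=0)
    channels = pd.read_csv(prefix.with_suffix(".channels.tsv"), sep="\t", index_col=0)
    channels["is_pooled"] = channels["is_pooled"].astype(bool)
    pairs = pd.read_csv(prefix.with_suffix(".pep2prot.tsv"), sep="\t")
    pep2prot = pairs.groupby("peptide", sort=False)["protein"].apply(tuple)
    pep2prot = pep2prot.reindex(abundance.index)
    return PeptideMatrix(
        abundance=abundance, channel_meta=channels, pep2prot=pep2prot
    )


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.rename_axis("sample_id").to_csv(path, **_TSV)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_protein_matrix(pm: ProteinMatrix, path: str | Path) -> None:
    pm.values.rename_axis("protein").to_csv(path, **_TSV)


def read_protein_matrix(path: str | Path) -> ProteinMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ProteinMatrix(values=values)


def write_signature(sig: SignedSignature, path: str | Path) -> None:
    df = pd.DataFrame({"entity": sig.entities, "sign": sig.sign.to_numpy()})
    if sig.magnitude is not None:
        df["magnitude"] = sig.magnitude.to_numpy()
    df.to_csv(path, index=False, **_TSV)


def read_signature(path: str | Path, label: str = "") -> SignedSignature:
    df = pd.read_csv(path, sep="\t")
    sign = df.set_index("entity")["sign"].astype(int)
    mag = df.set_index("entity")["magnitude"] if "magnitude" in df.columns else None
    return SignedSignature(sign=sign, magnitude=mag, label=label)


def read_edge_list(path: str | Path) -> InteractionGraph:
    """2- or 3-column TSV (protein_a, protein_b[, score]), String-export style."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:3])
    rename = dict(zip(cols, ["protein_a", "protein_b", "score"][: len(cols)]))
    return InteractionGraph(edges=df.rename(columns=rename))


def write_edge_list(graph: InteractionGraph, path: str | Path) -> None:
    graph.edges.to_csv(path, index=False, **_TSV)


def write_atlas(atlas: KnockdownAtlas, path: str | Path) -> None:
    atlas.table.to_csv(path, index=False, **_TSV)


def read_atlas(path: str | Path) -> KnockdownAtlas:
    return KnockdownAtlas(pd.read_csv(path, sep="\t"))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
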