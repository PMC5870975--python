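"""Versioned reference data: canonical gene names and reference gene orders."""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

CANONICAL_GENES_37 = None  # filled below

_NORM_DROP = str.maketrans("", "", " -_'")


def normalize_name(raw: str) -> str:
    """Normalisation applied before alias lookup (case/space/hyphen-blind)."""
    return raw.strip().upper().translate(_NORM_DROP)


def _data_lines(fname: str):
    text = resources.files("mitocomp.data").joinpath(fname).read_text()
    for line in text.splitlines():
        if line and not line.startswith("#"):
            yield line


@lru_cache(maxsize=None)
def _gene_table() -> list[dict]:
    rows = list(csv.DictReader(_data_lines("gene_names.tsv"), delimiter="\t"))
    return rows


@lru_cache(maxsize=None)
def alias_map() -> dict[str, str]:
    """normalised alias -> canonical name."""
    out: dict[str, str] = {}
    for row in _gene_table():
        canonical = row["canonical"]
        out[normalize_name(canonical)] = canonical
        for alias in row["aliases"].split("|"):
            out[normalize_name(alias)] = canonical
    return out


@lru_cache(maxsize=None)
def kind_map() -> dict[str, str]:
    return {row["canonical"]: row["kind"] for row in _gene_table()}


@lru_cache(maxsize=None)
def anticodon_map() -> dict[str, str]:
    """canonical tRNA name -> anticodon (RNA, 5'->3')."""
    return {
        row["canonical"]: row["anticodon"]
        for row in _gene_table()
        if row["kind"] == "tRNA"
    }


@lru_cache(maxsize=None)
def anticodon_to_trna() -> dict[str, str]:
    return {v: k for k, v in anticodon_map().items()}


def canonical_name(raw: str) -> str | None:
    """Map a raw annotation label to its canonical symbol, or None."""
    return alias_map().get(normalize_name(raw))


@lru_cache(maxsize=None)
def reference_order(order_name: str) -> tuple[tuple[str, str], ...]:
    """Reference gene order as ((gene, strand), ...), CR included last.

    ``order_name`` is ``"ditrysia"`` or ``"ancestral"``.
    """
    rows = [
        r
        for r in csv.DictReader(_data_lines("gene_orders.tsv"), delimiter="\t")
        if r["order_name"] == order_name
    ]
    if not rows:
        raise KeyError(f"unknown reference order {order_name!r}")
    rows.sort(key=lambda r: int(r["position"]))
    return tuple((r["gene"], r["strand"]) for r in rows)


def genes_37(order_name: str = "ditrysia") -> tuple[tuple[str, str], ...]:
    """The 37 genes (CR excluded) of a reference order, with strands."""
    return tuple((g, s) for g, s in reference_order(order_name) if g != "CR")


PCG_NAMES = tuple(
    sorted(r["canonical"] for r in _gene_table() if r["kind"] == "PCG")
)
TRNA_NAMES = tuple(
    sorted(r["canonical"] for r in _gene_table() if r["kind"] == "tRNA")
)
RRNA_NAMES = ("rrnL", "rrnS")
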