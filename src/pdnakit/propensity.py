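"""Tallying interface contacts into amino-acid interaction propensity tables.

Counts are raw (deliberately not normalized by amino-acid abundance, so
the natural abundance of residues at interfaces is retained). Percentages
are computed either over the grand total of a contact kind or over the
base-contact subtotal only.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .contacts import InteractionRecord

__all__ = [
    "FINE_TARGETS",
    "COARSE_TARGETS",
    "tally",
    "to_coarse",
    "normalize",
    "rank_amino_acids",
    "write_figure_tables",
]

FINE_TARGETS = ["phosphate", "sugar", "A", "C", "G", "T"]
COARSE_TARGETS = ["phosphate", "sugar", "bases"]
_BASES = ["A", "C", "G", "T"]


def tally(records: Iterable[InteractionRecord], kind: str | None = None) -> pd.DataFrame:
    """Integer contact counts per amino acid × target.

    Targets are phosphate, sugar, and the four bases. ``kind`` restricts
    to 'hbond' or 'vdw'; None counts both together.
    """
    counts: dict[tuple[str, str], int] = {}
    aas = set()
    for rec in records:
        if kind is not None and rec.kind != kind:
            continue
        aas.add(rec.aa_resname)
        key = (rec.aa_resname, rec.target)
        counts[key] = counts.get(key, 0) + 1
    table = pd.DataFrame(0, index=sorted(aas), columns=FINE_TARGETS, dtype=int)
    for (aa, target), n in counts.items():
        table.loc[aa, target] = n
    return table


def to_coarse(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the four base columns into a single 'bases' column."""
    out = pd.DataFrame(index=table.index)
    out["phosphate"] = table["phosphate"]
    out["sugar"] = table["sugar"]
    out["bases"] = table[_BASES].sum(axis=1)
    return out


def normalize(table: pd.DataFrame, mode: str = "all") -> pd.DataFrame:
    """Convert a count table to percentages.

    ``mode='all'`` divides by the grand total; ``mode='bases_only'``
    restricts to base targets and divides by the base subtotal. Raises on a
    zero denominator.
    """
    if mode == "all":
        total = float(table.values.sum())
        if total == 0:
            raise ValueError("cannot normalize: grand total is zero")
        return table / total * 100.0
    if mode == "bases_only":
        base_cols = [c for c in table.columns if c in _BASES]
        sub = table[base_cols]
        total = float(sub.values.sum())
        if total == 0:
            raise ValueError("cannot normalize: no base contacts")
        return sub / total * 100.0
    raise ValueError(f"unknown normalization mode {mode!r}")


def rank_amino_acids(table: pd.DataFrame) -> list[str]:
    """Amino acids in descending order of total contacts (ties alphabetical)."""
    totals = table.sum(axis=1)
    return sorted(totals.index, key=lambda aa: (-totals[aa], aa))


def write_figure_tables(
    hbond_counts: pd.DataFrame,
    vdw_counts: pd.DataFrame,
    out_dir: str | Path,
    hbond_sd: pd.DataFrame | None = None,
    vdw_sd: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the five summary CSVs (coarse/per-base percentages and ranking).

    Each CSV carries mean counts, SD (zero when a single table is supplied)
    and the percentage under the table's normalization mode.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    def _emit(name, counts, sd, mode):
        pct = normalize(counts, mode)
        sd_tbl = sd if sd is not None else counts * 0.0
        long = counts.stack().rename("mean").to_frame()
        long["sd"] = sd_tbl.stack()
        long["pct"] = pct.stack().reindex(long.index).fillna(0.0)
        long.index.names = ["amino_acid", "target"]
        path = out_dir / name
        long.reset_index().to_csv(path, index=False)
        written[name] = path

    _emit("fig1_hbond_pct.csv", to_coarse(hbond_counts),
          to_coarse(hbond_sd) if hbond_sd is not None else None, "all")
    _emit("fig2_vdw_pct.csv", to_coarse(vdw_counts),
          to_coarse(vdw_sd) if vdw_sd is not None else None, "all")
    _emit("fig3_base_hbond_pct.csv", hbond_counts, hbond_sd, "bases_only")
    _emit("fig4_base_vdw_pct.csv", vdw_counts, vdw_sd, "bases_only")

    summary = pd.DataFrame({
        "amino_acid": rank_amino_acids(hbond_counts + vdw_counts),
    })
    totals = (hbond_counts + vdw_counts).sum(axis=1)
    summary["total_contacts"] = summary["amino_acid"].map(totals)
    path = out_dir / "fig5_summary.csv"
    summary.to_csv(path, index=False)
    written["fig5_summary.csv"] = path
    return written
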