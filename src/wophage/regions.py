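"""Prophage-region assignment and the region x functional-class tally.

Prophage regions are defined as inclusive locus-number ranges on a genome's
tag prefix (e.g. the WOMelB1 block spans WD0565–WD0610).  Proteins encoded
by orphan phage genes fall outside every range and are tallied under
explicit orphan categories.  Region definitions are packaged as data
(``data/prophage_regions.tsv``) so users can extend them for other genomes.

``data/proteome_roster_synthetic.tsv`` is a synthetic per-protein roster
whose (region, class) cell counts realize the published detection tally for
the C/wStr1 prophage proteome; individual locus assignments within each
range are constructed, the cell counts are the reproduced facts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .io import round_half_up

#: Classes appearing in the tally, in report column order.
TALLY_CLASSES = ("HEAD", "BP", "TAIL", "REC", "REP", "MOD", "VIR", "UK")

STRUCTURAL_CLASSES = {"HEAD", "BP", "TAIL"}
DNA_PROCESS_CLASSES = {"REC", "REP", "MOD"}

#: Orphan tally categories, in report row order (after the ranged regions).
ORPHAN_CATEGORIES = ("PipOrphans", "MelOrphans", "Ana/SimOrphans")

NO_REGION = "NONE"

_LOCUS_RE = re.compile(r"^([A-Za-z]+)0*(\d+)$")


@dataclass(frozen=True)
class RegionDef:
    """One prophage region: locus-tag prefix plus an inclusive number range."""

    region_id: str
    prefix: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"{self.region_id}: lo {self.lo} > hi {self.hi}")

    def contains(self, prefix: str, number: int) -> bool:
        return prefix == self.prefix and self.lo <= number <= self.hi


def _validate_defs(defs: list[RegionDef]) -> None:
    by_prefix: dict[str, list[RegionDef]] = {}
    for d in defs:
        by_prefix.setdefault(d.prefix, []).append(d)
    for prefix, group in by_prefix.items():
        group = sorted(group, key=lambda d: d.lo)
        for a, b in zip(group, group[1:]):
            if b.lo <= a.hi:
                raise ValueError(
                    f"overlapping {prefix} ranges: {a.region_id} and {b.region_id}")


def parse_locus_tag(locus_tag: str) -> tuple[str, int]:
    """Split ``WD0612`` into (``"WD"``, 612); raises on unparsable tags."""
    m = _LOCUS_RE.match(locus_tag)
    if not m:
        raise ValueError(f"unparsable locus tag {locus_tag!r}")
    return m.group(1), int(m.group(2))


def assign_region(locus_tag: str, defs: list[RegionDef],
                  orphan_category: str = "") -> str:
    """Region id for a locus tag: first matching range wins.

    A tag outside every range falls to ``orphan_category`` when given (the
    orphan bucket declared for that genome), else ``NONE``.
    """
    prefix, number = parse_locus_tag(locus_tag)
    for d in defs:
        if d.contains(prefix, number):
            return d.region_id
    return orphan_category or NO_REGION


# ---------------------------------------------------------------------------
# packaged region data


def load_region_defs(path: str | Path | None = None) -> list[RegionDef]:
    """Load region definitions (packaged WO-prophage table when path omitted)."""
    if path is None:
        src = resources.files("wophage.data") / "prophage_regions.tsv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    defs = [RegionDef(str(r.region), str(r.prefix), int(r.lo), int(r.hi))
            for r in df.itertuples(index=False)]
    _validate_defs(defs)
    return defs


def load_proteome_roster() -> pd.DataFrame:
    """Synthetic per-protein roster realizing the published tally cell counts."""
    src = resources.files("wophage.data") / "proteome_roster_synthetic.tsv"
    with resources.as_file(src) as p:
        return pd.read_csv(p, sep="\t", keep_default_na=False)


def classify_proteins(df: pd.DataFrame, defs: list[RegionDef]
                      ) -> list[tuple[str, str, str]]:
    """(locus_tag, region, class) triples for a roster table.

    The roster needs ``locus_tag`` and ``functional_class`` columns; an
    optional ``orphan_category`` column supplies the fallback bucket for
    tags outside every range.
    """
    if "functional_class" not in df.columns and "class" in df.columns:
        df = df.rename(columns={"class": "functional_class"})
    triples = []
    has_orphan = "orphan_category" in df.columns
    for rec in df.itertuples(index=False):
        orphan = str(getattr(rec, "orphan_category", "")) if has_orphan else ""
        region = assign_region(str(rec.locus_tag), defs, orphan_category=orphan)
        triples.append((str(rec.locus_tag), region, str(rec.functional_class)))
    return triples


# ---------------------------------------------------------------------------
# tally


@dataclass
class RegionTally:
    """Region x class count matrix with row/column margins."""

    table: pd.DataFrame  # index: regions (+ "Total" row), columns: classes + "Total"

    @property
    def grand_total(self) -> int:
        return int(self.table.loc["Total", "Total"])

    def class_total(self, cls: str) -> int:
        return int(self.table.loc["Total", cls])

    def region_total(self, region: str) -> int:
        return int(self.table.loc[region, "Total"])


def tally(classified: list[tuple[str, str, str]],
          region_order: list[str] | None = None) -> RegionTally:
    """Tally classified proteins into a region x class matrix with margins.

    Each input triple (locus_tag, region, class) counts once; duplicate
    locus tags are an error, as is a class outside the eight tally classes.
    Row order follows ``region_order`` when given, else first appearance.
    """
    seen: set[str] = set()
    counts: dict[str, dict[str, int]] = {}
    order: list[str] = list(region_order or [])
    for locus, region, cls in classified:
        if cls not in TALLY_CLASSES:
            raise ValueError(f"unknown tally class {cls!r} for {locus}")
        if locus in seen:
            raise ValueError(f"duplicate locus tag {locus}")
        seen.add(locus)
        if region not in counts:
            counts[region] = {c: 0 for c in TALLY_CLASSES}
            if region not in order:
                order.append(region)
        counts[region][cls] += 1
    rows = [r for r in order if r in counts]
    table = pd.DataFrame(
        [[counts[r][c] for c in TALLY_CLASSES] for r in rows],
        index=rows, columns=list(TALLY_CLASSES), dtype=int,
    )
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return RegionTally(table)


def default_region_order() -> list[str]:
    """Published report row order: ranged regions then orphan categories."""
    return [d.region_id for d in load_region_defs()] + list(ORPHAN_CATEGORIES)


def class_percentages(t: RegionTally, class_subset: set[str]) -> int:
    """Percentage of the proteome in a class subset, rounded half-up."""
    unknown = class_subset - set(TALLY_CLASSES)
    if unknown:
        raise ValueError(f"unknown class(es): {sorted(unknown)}")
    if t.grand_total == 0:
        raise ValueError("empty tally")
    part = sum(t.class_total(c) for c in class_subset)
    return round_half_up(100.0 * part / t.grand_total)


def write_tally(t: RegionTally, path: str | Path) -> None:
    t.table.to_csv(path, sep="\t", index_label="region")
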