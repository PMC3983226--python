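"""Phosphosite tables: reading, identifier mapping, cross-study merging.

A phosphosite is a localized phosphorylation event identified by the triple
(protein accession, 1-based residue position, residue letter in {S, T, Y}).
Two quantitative phosphoproteomics studies of the same system typically
overlap only partially at the site level; this module merges such studies
into one site collection, applying a fold-change curation rule to sites
whose regulation status the studies disagree on: a site flagged regulated in
one study and detected-but-not-flagged in the other is promoted to regulated
if the non-flagging study's fold-change exceeds a threshold (default 1.4,
strictly greater).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

VALID_RESIDUES = frozenset("STY")

#: (protein accession, 1-based position, residue letter)
SiteKey = tuple[str, int, str]

_TRUTHY = {"1", "true", "yes", "y", "+", "t"}
_FALSY = {"0", "false", "no", "n", "-", "f", "", "nan", "none"}


class PhosphoDataError(ValueError):
    """Malformed phosphosite input (bad residue, position, or duplicate row)."""


@dataclass
class PhosphoSite:
    """One localized phosphorylation event with per-condition evidence.

    ``condition_fold`` maps a condition label to the stimulated/unstimulated
    abundance ratio (plain ratio, not log). ``regulated_in`` lists the
    conditions in which the site was called up-regulated. ``source`` records
    the contributing study labels. Per-study fold-changes survive merging in
    ``meta['folds_by_source']``.
    """

    protein: str
    position: int
    residue: str
    condition_fold: dict[str, float] = field(default_factory=dict)
    regulated_in: set[str] = field(default_factory=set)
    source: set[str] = field(default_factory=set)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.position, int) or self.position < 1:
            raise PhosphoDataError(
                f"position must be a 1-based integer >= 1, got {self.position!r}"
            )
        if self.residue not in VALID_RESIDUES:
            raise PhosphoDataError(
                f"residue must be one of S/T/Y, got {self.residue!r}"
            )

    @property
    def key(self) -> SiteKey:
        return (self.protein, self.position, self.residue)

    def copy(self) -> "PhosphoSite":
        return PhosphoSite(
            protein=self.protein,
            position=self.position,
            residue=self.residue,
            condition_fold=dict(self.condition_fold),
            regulated_in=set(self.regulated_in),
            source=set(self.source),
            meta={k: (dict(v) if isinstance(v, dict) else v) for k, v in self.meta.items()},
        )


#: A collection of sites keyed by their unique site key.
SiteCollection = dict[SiteKey, PhosphoSite]


@dataclass
class TableDialect:
    """Column mapping and unit conventions for one delimited phosphosite table.

    ``fold_columns`` / ``regulated_columns`` map condition labels to source
    column names. ``log2_folds`` declares that the source stores log2 ratios
    (converted to plain ratios on read); ``zero_based`` declares 0-based
    positions (converted to 1-based). ``strip_isoform`` removes an ``-N``
    isoform suffix from accessions so sites can be matched across studies
    that used different accession conventions.
    """

    protein: str = "protein"
    position: str = "position"
    residue: str = "residue"
    fold_columns: dict[str, str] = field(default_factory=dict)
    regulated_columns: dict[str, str] = field(default_factory=dict)
    source_label: str | None = None
    sep: str = "\t"
    log2_folds: bool = False
    zero_based: bool = False
    strip_isoform: bool = True
    meta_columns: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableDialect":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _clean_accession(acc: str, strip_isoform: bool) -> str:
    acc = str(acc).strip()
    if strip_isoform:
        acc = re.sub(r"-\d+$", "", acc)
    return acc


def _parse_flag(value) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise PhosphoDataError(f"cannot interpret regulation flag {value!r}")


def read_phosphosite_table(path: str | Path, dialect: TableDialect) -> SiteCollection:
    """Read one study's phosphosite table into a keyed site collection.

    Duplicate rows for the same site key are merged: per-condition
    fold-changes are unioned, and conflicting fold-changes for the same
    condition raise :class:`PhosphoDataError` with the offending row number.
    """
    frame = pd.read_csv(path, sep=dialect.sep, dtype=str)
    required = [dialect.protein, dialect.position, dialect.residue]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise PhosphoDataError(f"{path}: missing required columns {missing}")
    if not dialect.fold_columns and not dialect.regulated_columns:
        # canonical self-describing layout: fold_<condition> / regulated_<condition>
        dialect = TableDialect(**{**vars(dialect)})
        dialect.fold_columns = {
            c[len("fold_"):]: c for c in frame.columns if c.startswith("fold_")
        }
        dialect.regulated_columns = {
            c[len("regulated_"):]: c for c in frame.columns if c.startswith("regulated_")
        }

    sites: SiteCollection = {}
    for idx, row in frame.iterrows():
        rowno = idx + 2  # 1-based, counting the header line
        raw_pos = row[dialect.position]
        try:
            position = int(str(raw_pos).strip())
        except (TypeError, ValueError):
            raise PhosphoDataError(
                f"{path} row {rowno}: malformed position {raw_pos!r}"
            ) from None
        if dialect.zero_based:
            position += 1
        if position < 1:
            raise PhosphoDataError(f"{path} row {rowno}: position {position} < 1")
        residue = str(row[dialect.residue]).strip().upper()
        if residue not in VALID_RESIDUES:
            raise PhosphoDataError(
                f"{path} row {rowno}: unknown residue code {residue!r}"
            )
        protein = _clean_accession(row[dialect.protein], dialect.strip_isoform)

        folds: dict[str, float] = {}
        for cond, col in dialect.fold_columns.items():
            if col in frame.columns and pd.notna(row[col]) and str(row[col]).strip() != "":
                value = float(row[col])
                if dialect.log2_folds:
                    value = float(2.0 ** value)
                folds[cond] = value
        regulated: set[str] = set()
        for cond, col in dialect.regulated_columns.items():
            if col in frame.columns and pd.notna(row[col]):
                if _parse_flag(row[col]):
                    regulated.add(cond)
        meta = {c: row[c] for c in dialect.meta_columns if c in frame.columns}

        source = {dialect.source_label} if dialect.source_label else set()
        site = PhosphoSite(protein, position, residue, folds, regulated, source, meta)
        if site.key in sites:
            existing = sites[site.key]
            for cond, value in folds.items():
                if cond in existing.condition_fold and existing.condition_fold[cond] != value:
                    raise PhosphoDataError(
                        f"{path} row {rowno}: conflicting fold-change for "
                        f"{site.key} condition {cond!r}: "
                        f"{existing.condition_fold[cond]} vs {value}"
                    )
                existing.condition_fold[cond] = value
            existing.regulated_in |= regulated
            existing.source |= source
            existing.meta.update(meta)
        else:
            sites[site.key] = site
    return sites


def write_phosphosite_table(
    sites: SiteCollection,
    path: str | Path,
    conditions: Iterable[str] | None = None,
    sep: str = "\t",
) -> None:
    """Write a site collection back to delimited text (round-trip safe)."""
    if conditions is None:
        conditions = sorted({c for s in sites.values() for c in s.condition_fold})
    conditions = list(conditions)
    rows = []
    for site in sites.values():
        row = {
            "protein": site.protein,
            "position": site.position,
            "residue": site.residue,
        }
        for cond in conditions:
            row[f"fold_{cond}"] = site.condition_fold.get(cond, "")
            row[f"regulated_{cond}"] = int(cond in site.regulated_in)
        row["source"] = ";".join(sorted(site.source))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def dialect_for_written_table(conditions: Iterable[str], source_label: str | None = None) -> TableDialect:
    """Dialect matching :func:`write_phosphosite_table` output."""
    conditions = list(conditions)
    return TableDialect(
        fold_columns={c: f"fold_{c}" for c in conditions},
        regulated_columns={c: f"regulated_{c}" for c in conditions},
        source_label=source_label,
    )


@dataclass
class IdMapping:
    """Accession translation between namespaces (e.g. IPI -> UniProt).

    The mapping is a function: each source accession maps to at most one
    target accession; sources with no target live in ``unmapped``.
    """

    entries: dict[str, str] = field(default_factory=dict)
    unmapped: set[str] = field(default_factory=set)

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "IdMapping":
        frame = pd.read_csv(path, sep=sep, dtype=str, header=0)
        if frame.shape[1] < 2:
            raise PhosphoDataError(f"{path}: mapping file needs two columns")
        entries: dict[str, str] = {}
        unmapped: set[str] = set()
        for _, row in frame.iterrows():
            src = str(row.iloc[0]).strip()
            dst = row.iloc[1]
            if pd.isna(dst) or str(dst).strip() == "":
                unmapped.add(src)
                continue
            dst = str(dst).strip()
            if src in entries and entries[src] != dst:
                raise PhosphoDataError(f"{path}: {src} maps to both {entries[src]} and {dst}")
            entries[src] = dst
        return cls(entries=entries, unmapped=unmapped)


def apply_id_mapping(
    sites: SiteCollection,
    mapping: IdMapping,
    on_unmapped: str = "drop",
) -> tuple[SiteCollection, list[SiteKey]]:
    """Translate protein accessions to the mapping's target namespace.

    ``on_unmapped`` is one of ``drop`` (return dropped keys separately),
    ``keep`` (pass through flagged with ``meta['unmapped']``), or ``error``.
    """
    if on_unmapped not in {"drop", "keep", "error"}:
        raise ValueError(f"unknown on_unmapped policy {on_unmapped!r}")
    out: SiteCollection = {}
    dropped: list[SiteKey] = []
    missing: list[str] = []
    for key, site in sites.items():
        target = mapping.entries.get(site.protein)
        if target is None:
            if on_unmapped == "drop":
                dropped.append(key)
                continue
            if on_unmapped == "error":
                missing.append(site.protein)
                continue
            kept = site.copy()
            kept.meta["unmapped"] = True
            out[kept.key] = kept
            continue
        mapped = site.copy()
        mapped.protein = target
        out[mapped.key] = mapped
    if missing:
        raise PhosphoDataError(
            "unmapped accessions under policy=error: " + ", ".join(sorted(set(missing)))
        )
    return out, dropped


@dataclass
class MergeReport:
    """Counts produced while merging two studies' site collections."""

    n_sites_total: int = 0
    n_proteins_total: int = 0
    n_sites_overlap: int = 0
    n_proteins_overlap: int = 0
    n_borderline_examined: int = 0
    n_borderline_promoted: int = 0
    per_condition_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_sites_total": self.n_sites_total,
            "n_proteins_total": self.n_proteins_total,
            "n_sites_overlap": self.n_sites_overlap,
            "n_proteins_overlap": self.n_proteins_overlap,
            "n_borderline_examined": self.n_borderline_examined,
            "n_borderline_promoted": self.n_borderline_promoted,
            "per_condition_counts": {
                c: {"n_sites": s, "n_proteins": p}
                for c, (s, p) in self.per_condition_counts.items()
            },
        }

    def to_text(self) -> str:
        lines = [
            f"sites_total\t{self.n_sites_total}",
            f"proteins_total\t{self.n_proteins_total}",
            f"sites_overlap\t{self.n_sites_overlap}",
            f"proteins_overlap\t{self.n_proteins_overlap}",
            f"borderline_examined\t{self.n_borderline_examined}",
            f"borderline_promoted\t{self.n_borderline_promoted}",
        ]
        for cond in sorted(self.per_condition_counts):
            s, p = self.per_condition_counts[cond]
            lines.append(f"condition[{cond}]_sites\t{s}")
            lines.append(f"condition[{cond}]_proteins\t{p}")
        return "\n".join(lines) + "\n"


_ACCESSION_STYLES = (
    ("ipi", re.compile(r"^IPI\d+")),
    ("uniprot", re.compile(r"^[OPQ][0-9][A-Z0-9]{3}[0-9]$|^[A-NR-Z][0-9][A-Z][A-Z0-9]{2}[0-9]$")),
)


def _accession_style(acc: str) -> str:
    for name, pattern in _ACCESSION_STYLES:
        if pattern.match(acc):
            return name
    return "other"


def _check_shared_namespace(a: SiteCollection, b: SiteCollection) -> None:
    styles_a = {_accession_style(s.protein) for s in a.values()} - {"other"}
    styles_b = {_accession_style(s.protein) for s in b.values()} - {"other"}
    if styles_a and styles_b and styles_a.isdisjoint(styles_b):
        raise PhosphoDataError(
            f"accession namespaces look mixed ({sorted(styles_a)} vs {sorted(styles_b)}); "
            "run apply_id_mapping first"
        )


def merge_studies(
    study_a: SiteCollection,
    study_b: SiteCollection,
    fold_threshold: float = 1.4,
    demote_unconfirmed: bool = False,
) -> tuple[SiteCollection, MergeReport]:
    """Union two studies on site keys with borderline-site curation.

    For a site flagged regulated in condition C by one study and detected in
    C (fold-change recorded) but not flagged by the other, the conflict is
    counted as borderline examined; it is confirmed (promoted) iff the
    non-flagging study's fold-change is strictly greater than
    ``fold_threshold``. By default the flagging study's call stands either
    way (union semantics) and the outcome is recorded in
    ``meta['borderline']``; with ``demote_unconfirmed=True`` an unconfirmed
    conflict removes the regulated flag for that condition. A conflict where
    the non-flagging study recorded no fold-change for C cannot be examined;
    the flag always stands there.
    """
    _check_shared_namespace(study_a, study_b)
    merged: SiteCollection = {}
    report = MergeReport()

    for key in study_a.keys() | study_b.keys():
        in_a, in_b = study_a.get(key), study_b.get(key)
        if in_a is None or in_b is None:
            merged[key] = (in_a or in_b).copy()
            continue
        site = in_a.copy()
        site.source |= in_b.source
        site.regulated_in |= in_b.regulated_in
        folds_by_source = {
            **{s: dict(in_a.condition_fold) for s in (sorted(in_a.source) or ["a"])[:1]},
            **{s: dict(in_b.condition_fold) for s in (sorted(in_b.source) or ["b"])[:1]},
        }
        site.meta["folds_by_source"] = folds_by_source
        for cond, value in in_b.condition_fold.items():
            site.condition_fold[cond] = max(site.condition_fold.get(cond, value), value)
        site.meta.update({k: v for k, v in in_b.meta.items() if k not in site.meta})

        # borderline curation: regulated in one study, detected-not-regulated
        # in the other for the same condition
        for flagging, other in ((in_a, in_b), (in_b, in_a)):
            for cond in flagging.regulated_in - other.regulated_in:
                if cond not in other.condition_fold:
                    continue  # not detected in that condition: nothing to examine
                report.n_borderline_examined += 1
                confirmed = other.condition_fold[cond] > fold_threshold
                if confirmed:
                    report.n_borderline_promoted += 1
                elif demote_unconfirmed:
                    site.regulated_in.discard(cond)
                site.meta.setdefault("borderline", {})[cond] = (
                    "promoted" if confirmed else "not_promoted"
                )
        merged[key] = site

    # Overlap bookkeeping
    report.n_sites_total = len(merged)
    report.n_proteins_total = len({k[0] for k in merged})
    report.n_sites_overlap = len(study_a.keys() & study_b.keys())
    report.n_proteins_overlap = len(
        {k[0] for k in study_a} & {k[0] for k in study_b}
    )
    conditions = {c for s in merged.values() for c in s.regulated_in}
    for cond in sorted(conditions):
        regulated = [s for s in merged.values() if cond in s.regulated_in]
        report.per_condition_counts[cond] = (
            len(regulated),
            len({s.protein for s in regulated}),
        )
    return merged, report


def regulated_subset(sites: SiteCollection, condition: str) -> SiteCollection:
    """Sites flagged regulated in one condition."""
    return {k: s for k, s in sites.items() if condition in s.regulated_in}


def overlap_stats(study_a: SiteCollection, study_b: SiteCollection) -> MergeReport:
    """Site- and protein-level intersection counts between two studies."""
    _check_shared_namespace(study_a, study_b)
    report = MergeReport()
    report.n_sites_total = len(study_a.keys() | study_b.keys())
    report.n_proteins_total = len({k[0] for k in study_a} | {k[0] for k in study_b})
    report.n_sites_overlap = len(study_a.keys() & study_b.keys())
    report.n_proteins_overlap = len({k[0] for k in study_a} & {k[0] for k in study_b})
    return report


def residue_composition(sites: SiteCollection) -> dict[str, tuple[int, float]]:
    """Per-residue (count, fraction); fractions sum to 1."""
    if not sites:
        raise PhosphoDataError("residue_composition: empty site collection")
    counts: dict[str, int] = {}
    for site in sites.values():
        counts[site.residue] = counts.get(site.residue, 0) + 1
    total = len(sites)
    return {r: (c, c / total) for r, c in sorted(counts.items())}


def multiplicity_distribution(
    sites: SiteCollection,
) -> tuple[dict[int, int], float, float]:
    """Distribution of phosphosites per protein.

    Returns (``{k: number of proteins with exactly k sites}``, fraction of
    proteins with >= 2 sites, mean sites per protein).
    """
    if not sites:
        raise PhosphoDataError("multiplicity_distribution: empty site collection")
    per_protein: dict[str, int] = {}
    for key in sites:
        per_protein[key[0]] = per_protein.get(key[0], 0) + 1
    dist: dict[int, int] = {}
    for count in per_protein.values():
        dist[count] = dist.get(count, 0) + 1
    n_proteins = len(per_protein)
    multi = sum(n for k, n in dist.items() if k >= 2) / n_proteins
    mean = len(sites) / n_proteins
    return dict(sorted(dist.items())), multi, mean
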