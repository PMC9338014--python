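"""Gene annotation and protein-complex compendium handling.

The compendium maps curated protein complexes to their subunit proteins; the
annotation maps each gene/protein to one of the 16 yeast chromosomes.  Both
drive the counting and grouping used throughout the pipeline: how many
complexes have a subunit encoded on a replaced chromosome, and whether a
quantified protein is a "chr-complex" protein (member of at least one complex
exposed to a replaced-chromosome subunit), a "non-chr-complex" protein, or not
a complex subunit at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

NON_COMPLEX = "non_complex"
CHR_COMPLEX = "chr_complex"
NON_CHR_COMPLEX = "non_chr_complex"

_ROMAN = {
    "I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6, "VII": 7, "VIII": 8,
    "IX": 9, "X": 10, "XI": 11, "XII": 12, "XIII": 13, "XIV": 14, "XV": 15,
    "XVI": 16,
}


class AnnotationError(ValueError):
    """Malformed or incomplete annotation / compendium input."""


def parse_chromosome(value) -> int:
    """Parse a chromosome label into an Arabic integer 1-16.

    Accepts integers, digit strings, Roman numerals (``XVI``) and common
    prefixed forms (``chrXVI``, ``chr16``).
    """
    if isinstance(value, (int,)) and not isinstance(value, bool):
        chrom = int(value)
    else:
        s = str(value).strip()
        for prefix in ("chromosome", "chrom", "chr"):
            if s.lower().startswith(prefix):
                s = s[len(prefix):]
                break
        s = s.strip().upper()
        if s.isdigit():
            chrom = int(s)
        elif s in _ROMAN:
            chrom = _ROMAN[s]
        else:
            raise AnnotationError(f"unrecognized chromosome label: {value!r}")
    if not 1 <= chrom <= 16:
        raise AnnotationError(f"chromosome {chrom} outside 1-16")
    return chrom


def load_annotation(path) -> pd.DataFrame:
    """Load a gene -> protein -> chromosome table (TSV with header).

    Required columns: ``gene_id``, ``protein_id``, ``chromosome``; optional
    ``length_bp``.  Chromosome labels may be Arabic or Roman and are
    normalized to integers.  gene_id and protein_id must each be unique
    (1:1 mapping).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "protein_id", "chromosome"} - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation missing columns: {sorted(missing)}")
    df = df.copy()
    df["chromosome"] = df["chromosome"].map(parse_chromosome)
    if "length_bp" in df.columns:
        df["length_bp"] = pd.to_numeric(df["length_bp"])
    validate_annotation(df)
    return df


def validate_annotation(annot: pd.DataFrame) -> None:
    for col in ("gene_id", "protein_id"):
        dup = annot[col][annot[col].duplicated()]
        if not dup.empty:
            raise AnnotationError(f"duplicate {col}: {sorted(set(dup))[:5]}")
    bad = annot.loc[~annot["chromosome"].between(1, 16), "chromosome"]
    if not bad.empty:
        raise AnnotationError(f"chromosomes outside 1-16: {sorted(set(bad))}")


def protein_chromosome_map(annot: pd.DataFrame) -> pd.Series:
    """Series mapping protein_id -> chromosome (int)."""
    return annot.set_index("protein_id")["chromosome"]


def protein_gene_map(annot: pd.DataFrame) -> pd.Series:
    return annot.set_index("protein_id")["gene_id"]


@dataclass
class ComplexCompendium:
    """Curated complex -> subunit membership.

    ``members`` maps complex_id to the set of member protein_ids.  Complexes
    that arrive with fewer than two members are retained but flagged (they are
    excluded from complex counting, which concerns physical assemblies).
    """

    members: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    removed_reasons: dict[str, str] = field(default_factory=dict)

    @property
    def complex_ids(self) -> list[str]:
        return list(self.members)

    @property
    def n_complexes(self) -> int:
        return len(self.members)

    @property
    def subunits(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.members.values():
            out |= m
        return frozenset(out)

    @property
    def flagged_small(self) -> frozenset[str]:
        return frozenset(c for c, m in self.members.items() if len(m) < 2)

    def countable_ids(self) -> list[str]:
        """Complexes with >=2 members (physical assemblies)."""
        return [c for c, m in self.members.items() if len(m) >= 2]

    def complexes_of(self, protein_id: str) -> list[str]:
        return [c for c, m in self.members.items() if protein_id in m]

    def membership_frame(self) -> pd.DataFrame:
        rows = [(c, p) for c, m in self.members.items() for p in sorted(m)]
        return pd.DataFrame(rows, columns=["complex_id", "protein_id"])


def compendium_from_mapping(mapping: Mapping[str, Iterable[str]],
                            names: Mapping[str, str] | None = None) -> ComplexCompendium:
    members = {str(c): frozenset(map(str, ms)) for c, ms in mapping.items()}
    return ComplexCompendium(members=members, names=dict(names or {}))


def load_compendium(path) -> ComplexCompendium:
    """Load a complex membership TSV (one row per complex/subunit pair).

    Required columns: ``complex_id``, ``protein_id``; optional ``name``,
    ``provenance_flag``, ``reason``.  Duplicate membership rows are collapsed.
    Complexes with a single member are retained but flagged with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"complex_id", "protein_id"} - set(df.columns)
    if missing:
        raise AnnotationError(f"compendium missing columns: {sorted(missing)}")
    df = df.drop_duplicates(subset=["complex_id", "protein_id"])
    members: dict[str, frozenset[str]] = {}
    for cid, grp in df.groupby("complex_id", sort=False):
        members[cid] = frozenset(grp["protein_id"])
    names = {}
    if "name" in df.columns:
        names = df.dropna(subset=["name"]).set_index("complex_id")["name"].to_dict()
    provenance = {}
    if "provenance_flag" in df.columns:
        provenance = (df.dropna(subset=["provenance_flag"])
                      .set_index("complex_id")["provenance_flag"].to_dict())
    removed = {}
    if "reason" in df.columns:
        removed = df.dropna(subset=["reason"]).set_index("complex_id")["reason"].to_dict()
    comp = ComplexCompendium(members=members, names=names,
                             provenance=provenance, removed_reasons=removed)
    small = comp.flagged_small
    if small:
        logger.warning("%d complexes have <2 members and are flagged: %s",
                       len(small), sorted(small)[:5])
    logger.info("loaded compendium: %d complexes, %d distinct subunits",
                comp.n_complexes, len(comp.subunits))
    return comp


def _replaced_set(replaced) -> frozenset[int]:
    if isinstance(replaced, int):
        replaced = {replaced}
    return frozenset(parse_chromosome(c) for c in replaced)


def _check_annotated(compendium: ComplexCompendium, chrom: pd.Series) -> None:
    unknown = sorted(compendium.subunits - set(chrom.index))
    if unknown:
        raise AnnotationError(
            f"{len(unknown)} compendium members lack annotation: {unknown[:10]}")


def complexes_on_chromosomes(compendium: ComplexCompendium, annot: pd.DataFrame,
                             replaced) -> set[str]:
    """Countable complexes with >=1 member encoded on any replaced chromosome."""
    rep = _replaced_set(replaced)
    chrom = protein_chromosome_map(annot)
    _check_annotated(compendium, chrom)
    out = set()
    for cid in compendium.countable_ids():
        if any(chrom[p] in rep for p in compendium.members[cid]):
            out.add(cid)
    return out


def count_complexes_on_chromosomes(compendium: ComplexCompendium,
                                   annot: pd.DataFrame, replaced) -> int:
    """Number of unique complexes having a subunit on a replaced chromosome."""
    return len(complexes_on_chromosomes(compendium, annot, replaced))


def complex_protein_ratio(compendium: ComplexCompendium, annot: pd.DataFrame,
                          replaced) -> float:
    """Fraction of replaced-chromosome proteins that are complex subunits."""
    rep = _replaced_set(replaced)
    chrom = protein_chromosome_map(annot)
    _check_annotated(compendium, chrom)
    on_replaced = set(chrom.index[chrom.isin(rep)])
    if not on_replaced:
        raise AnnotationError(f"no annotated proteins on chromosomes {sorted(rep)}")
    subunits = set()
    for cid in compendium.countable_ids():
        subunits |= compendium.members[cid]
    return len(on_replaced & subunits) / len(on_replaced)


def assign_protein_group(protein_id: str, compendium: ComplexCompendium,
                         annot: pd.DataFrame, replaced,
                         both_precedence: str = CHR_COMPLEX) -> str:
    """Label one protein as chr_complex / non_chr_complex / non_complex.

    A protein in at least one complex with a replaced-chromosome subunit is
    ``chr_complex`` (default precedence; any such membership exposes the
    protein to a chimeric assembly).  Set ``both_precedence=NON_CHR_COMPLEX``
    to flip the precedence for dual-membership proteins.
    """
    return assign_protein_groups([protein_id], compendium, annot, replaced,
                                 both_precedence=both_precedence).iloc[0]


def assign_protein_groups(protein_ids: Iterable[str],
                          compendium: ComplexCompendium, annot: pd.DataFrame,
                          replaced, both_precedence: str = CHR_COMPLEX) -> pd.Series:
    """Vectorized group labels for a set of quantified proteins."""
    if both_precedence not in (CHR_COMPLEX, NON_CHR_COMPLEX):
        raise ValueError(f"bad precedence {both_precedence!r}")
    chr_cplx = complexes_on_chromosomes(compendium, annot, replaced)
    in_chr: set[str] = set()
    in_nonchr: set[str] = set()
    for cid in compendium.countable_ids():
        if cid in chr_cplx:
            in_chr |= compendium.members[cid]
        else:
            in_nonchr |= compendium.members[cid]
    labels = {}
    for p in protein_ids:
        if p in in_chr and p in in_nonchr:
            labels[p] = both_precedence
        elif p in in_chr:
            labels[p] = CHR_COMPLEX
        elif p in in_nonchr:
            labels[p] = NON_CHR_COMPLEX
        else:
            labels[p] = NON_COMPLEX
    ids = list(protein_ids)
    return pd.Series([labels[p] for p in ids], index=ids, name="group")
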