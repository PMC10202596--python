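"""Pseudogenizing-lesion detection and critical-site screening.

Scans aligned coding sequences for the disruptions that mark a pseudogene —
premature stop codons and frame-shifting indels — and screens a catalog of
functionally critical residues (reference-protein numbering, e.g. the human
PON1 catalytic-calcium ligand N270) for substitutions.

Coordinates are 1-based in reference numbering throughout; alignment columns
never leak into reports. Stops are read in the reference frame (aligned
codon columns), so synonymous divergence elsewhere never changes a call.
Each maximal gap run is treated as an independent lesion: two 1-nt gaps that
jointly restore frame are still two frameshifts.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .alignment import CodonAlignment, ProteinAlignment
from .genetics import STOP_CODONS, translate_codon

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

#: the ten major active-site residues screened in the study, human PON1
#: (UniProt P27169) numbering
DEFAULT_PON1_CATALOG: "SiteCatalog"


@dataclass(frozen=True)
class CatalogEntry:
    ref_position: int
    ref_residue: str
    annotation: str = ""


@dataclass
class SiteCatalog:
    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        positions = [e.ref_position for e in self.entries]
        if any(p <= 0 for p in positions):
            raise ValueError("catalog positions must be strictly positive")
        if len(set(positions)) != len(positions):
            raise ValueError("catalog positions must be unique")
        for e in self.entries:
            if e.ref_residue not in _AA_LETTERS:
                raise ValueError(f"{e.ref_residue!r} is not a standard amino-acid letter")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, str] | tuple[int, str, str]]) -> "SiteCatalog":
        entries = []
        for pair in pairs:
            pos, res, *rest = pair
            entries.append(CatalogEntry(int(pos), str(res), rest[0] if rest else ""))
        return cls(tuple(entries))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SiteCatalog":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                entries.append(
                    CatalogEntry(
                        int(row["ref_position"]), row["ref_residue"],
                        row.get("annotation", "") or "",
                    )
                )
        return cls(tuple(entries))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["ref_position", "ref_residue", "annotation"])
            for e in self.entries:
                w.writerow([e.ref_position, e.ref_residue, e.annotation])


DEFAULT_PON1_CATALOG = SiteCatalog.from_pairs(
    [
        (71, "Y", "active site wall"),
        (117, "I", "crucial for catalytic activity"),
        (134, "H", "reduced activity when substituted"),
        (155, "H", "reduced activity when substituted"),
        (184, "H", "part of the active site"),
        (192, "R", "active site wall"),
        (202, "W", "reduced activity when substituted"),
        (222, "F", "active site wall"),
        (270, "N", "catalytic calcium binding"),
        (304, "V", "reduced activity when substituted"),
    ]
)


@dataclass(frozen=True)
class Lesion:
    species: str
    kind: str  # premature_stop | frameshift | critical_site_sub | splice_disruption
    ref_position: int
    detail: str = ""
    annotation: str = ""

    KINDS = ("premature_stop", "frameshift", "critical_site_sub", "splice_disruption")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.ref_position <= 0:
            raise ValueError("ref_position must be 1-based positive")


@dataclass
class LesionReport:
    lesions_by_species: dict[str, list[Lesion]] = field(default_factory=dict)

    def add(self, lesion: Lesion) -> None:
        self.lesions_by_species.setdefault(lesion.species, []).append(lesion)

    def all_lesions(self) -> list[Lesion]:
        return [l for ls in self.lesions_by_species.values() for l in ls]

    def summary(self) -> dict[str, dict[str, bool]]:
        out = {}
        for sp, ls in self.lesions_by_species.items():
            out[sp] = dict(
                any_lesion=any(l.kind in ("premature_stop", "frameshift", "splice_disruption") for l in ls),
                any_critical_sub=any(l.kind == "critical_site_sub" for l in ls),
            )
        return out

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["species", "kind", "ref_position", "detail", "annotation"])
            for l in sorted(self.all_lesions(), key=lambda l: (l.species, l.ref_position)):
                w.writerow([l.species, l.kind, l.ref_position, l.detail, l.annotation])

    def write_json_summary(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# coordinate mapping


def map_reference_coordinates(
    alignment: CodonAlignment | ProteinAlignment,
    ref_species: str | None = None,
) -> dict[int, dict[str, str]]:
    """Map each reference residue position to the residue every species
    carries at that aligned column ('-' for an explicit gap state).

    Codon alignments are translated column-triplet-wise first; reference
    numbering is defined by the reference sequence's ungapped positions.
    """
    prot = alignment.to_protein() if isinstance(alignment, CodonAlignment) else alignment
    ref = ref_species or prot.ref_species
    if ref is None or ref not in prot.seqs:
        raise ValueError(f"reference species {ref!r} not present in alignment")
    refseq = prot.seqs[ref]
    mapping: dict[int, dict[str, str]] = {}
    pos = 0
    for col, ch in enumerate(refseq):
        if ch == "-":
            continue
        pos += 1
        mapping[pos] = {sp: prot.seqs[sp][col] for sp in prot.seqs}
    return mapping


# ---------------------------------------------------------------------------
# coding-lesion detection


def _ref_codon_columns(ref_aligned: str) -> list[tuple[int, int, int] | None]:
    """Aligned column triple for each reference codon (reference ungapped
    nucleotide coordinates define the frame)."""
    cols = [i for i, ch in enumerate(ref_aligned) if ch != "-"]
    triples = []
    for c in range(len(cols) // 3):
        triples.append((cols[3 * c], cols[3 * c + 1], cols[3 * c + 2]))
    return triples


def detect_coding_lesions(
    alignment: CodonAlignment,
    species: str | Sequence[str] | None = None,
    ref_species: str | None = None,
) -> list[Lesion]:
    """Premature stops (reference frame) and frame-shifting gap runs.

    For each query species: every aligned reference codon whose query triplet
    is a stop before the terminal codon is a ``premature_stop``; every
    maximal gap run, in the query or in the reference (insertion), whose
    length mod 3 != 0 is a ``frameshift``. Positions are 1-based reference
    codon numbers.
    """
    ref = ref_species or alignment.ref_species
    if ref is None or ref not in alignment.seqs:
        raise ValueError(f"reference species {ref!r} not present in alignment")
    ref_aligned = alignment.seqs[ref]
    triples = _ref_codon_columns(ref_aligned)
    n_ref_codons = len(triples)
    # validate reference: in frame with no internal stop
    for c, (a, b, d) in enumerate(triples, start=1):
        codon = ref_aligned[a] + ref_aligned[b] + ref_aligned[d]
        if codon in STOP_CODONS and c < n_ref_codons:
            raise ValueError(f"reference contains internal stop at codon {c}")
    if species is None:
        targets = [sp for sp in alignment.species if sp != ref]
    elif isinstance(species, str):
        targets = [species]
    else:
        targets = list(species)

    # precompute reference codon index per aligned column (for gap positions)
    col_to_codon = {}
    for c, (a, b, d) in enumerate(triples, start=1):
        for col in (a, b, d):
            col_to_codon[col] = c
    ref_cols = sorted(col_to_codon)

    lesions: list[Lesion] = []
    for sp in targets:
        seq = alignment.seqs[sp]
        # premature stops in reference frame
        for c, (a, b, d) in enumerate(triples, start=1):
            codon = seq[a] + seq[b] + seq[d]
            if codon in STOP_CODONS and c < n_ref_codons:
                lesions.append(Lesion(sp, "premature_stop", c, detail=codon))
        # frameshifts: maximal gap runs in the query over reference columns
        for m in re.finditer(r"-+", seq):
            run_cols = [col for col in range(m.start(), m.end()) if ref_aligned[col] != "-"]
            if not run_cols:
                continue  # gap aligned to reference gap: no sequence lost
            if len(run_cols) % 3 != 0:
                pos = col_to_codon.get(run_cols[0])
                if pos is None:  # beyond reference frame remainder
                    pos = n_ref_codons
                lesions.append(
                    Lesion(sp, "frameshift", pos, detail=f"deletion of {len(run_cols)} nt")
                )
        # insertions: maximal gap runs in the reference where query has sequence
        for m in re.finditer(r"-+", ref_aligned):
            ins_cols = [col for col in range(m.start(), m.end()) if seq[col] != "-"]
            if not ins_cols:
                continue
            if len(ins_cols) % 3 != 0:
                prev_ref = [col for col in ref_cols if col < m.start()]
                pos = col_to_codon[prev_ref[-1]] if prev_ref else 1
                lesions.append(
                    Lesion(sp, "frameshift", pos, detail=f"insertion of {len(ins_cols)} nt")
                )
    return lesions


def detect_critical_site_substitutions(
    alignment: CodonAlignment | ProteinAlignment,
    catalog: SiteCatalog = DEFAULT_PON1_CATALOG,
    ref_species: str | None = None,
) -> list[Lesion]:
    """One ``critical_site_sub`` per (species, site) whose residue differs
    from the catalog's reference residue. Deleted sites are reported with
    detail ``"deleted"``; ambiguous residues (X/N) are reported as
    ``"unresolved"`` and never counted as substitutions."""
    mapping = map_reference_coordinates(alignment, ref_species)
    n_ref = max(mapping) if mapping else 0
    lesions: list[Lesion] = []
    for entry in catalog:
        if entry.ref_position > n_ref:
            raise ValueError(
                f"catalog position {entry.ref_position} beyond reference length {n_ref}"
            )
        residues = mapping[entry.ref_position]
        for sp, res in residues.items():
            if res == entry.ref_residue:
                continue
            if res == "-":
                detail = "deleted"
            elif res == "X":  # untranslatable codon (ambiguity), not a substitution call
                detail = "unresolved"
            else:
                detail = res
            lesions.append(
                Lesion(sp, "critical_site_sub", entry.ref_position,
                       detail=detail, annotation=entry.annotation)
            )
    return lesions


def scan_alignment(
    alignment: CodonAlignment,
    catalog: SiteCatalog = DEFAULT_PON1_CATALOG,
    ref_species: str | None = None,
    include_reference: bool = False,
) -> LesionReport:
    """Full scan: coding lesions plus critical-site substitutions."""
    report = LesionReport()
    ref = ref_species or alignment.ref_species
    for lesion in detect_coding_lesions(alignment, ref_species=ref):
        report.add(lesion)
    for lesion in detect_critical_site_substitutions(alignment, catalog, ref):
        if (lesion.species != ref or include_reference) and lesion.detail != "unresolved":
            report.add(lesion)
    for sp in alignment.species:
        if sp != ref:
            report.lesions_by_species.setdefault(sp, [])
    return report


# ---------------------------------------------------------------------------
# splice sites


def detect_splice_disruptions(
    sequences: dict[str, str],
    exons: Sequence[tuple[int, int]],
    ref_species: str | None = None,
) -> list[Lesion]:
    """Canonical GT–AG check at every intron of an annotated gene.

    ``sequences`` maps species to unaligned genomic sequence in a shared
    coordinate system; ``exons`` are 1-based inclusive (start, end) pairs in
    those coordinates. Any donor site not ``GT`` or acceptor not ``AG`` is a
    ``splice_disruption`` at the intron's 1-based index. Without exon
    annotations splice checks are simply not performed.
    """
    exons = sorted(tuple(map(int, e)) for e in exons)
    for (s1, e1), (s2, _) in zip(exons, exons[1:]):
        if not (s1 <= e1 < s2):
            raise ValueError("exons must be ordered, non-overlapping 1-based ranges")
        if s2 - e1 < 5:
            raise ValueError(f"intron between {e1} and {s2} too short for GT..AG")
    lesions: list[Lesion] = []
    for species, seq in sequences.items():
        if species == ref_species:
            continue
        for k, ((_, end), (start2, _)) in enumerate(zip(exons, exons[1:]), start=1):
            donor = seq[end:end + 2].upper()
            acceptor = seq[start2 - 3:start2 - 1].upper()
            if donor != "GT":
                lesions.append(
                    Lesion(species, "splice_disruption", k, detail=f"donor {donor or '??'}")
                )
            if acceptor != "AG":
                lesions.append(
                    Lesion(species, "splice_disruption", k, detail=f"acceptor {acceptor or '??'}")
                )
    return lesions


# ---------------------------------------------------------------------------
# conservation


def compute_site_conservation(
    alignment: CodonAlignment | ProteinAlignment,
    ref_position: int,
    group: Sequence[str],
    ref_species: str | None = None,
) -> float:
    """Fraction of the group matching the group-consensus residue at a site.

    The consensus is the modal residue among group members (gaps never form
    the consensus; ties break alphabetically for determinism); gap states
    count as non-matching.
    """
    if not group:
        raise ValueError("group must be nonempty")
    mapping = map_reference_coordinates(alignment, ref_species)
    if ref_position not in mapping:
        raise ValueError(f"reference position {ref_position} not mapped")
    residues = mapping[ref_position]
    missing = [sp for sp in group if sp not in residues]
    if missing:
        raise KeyError(f"species not in alignment: {missing}")
    observed = [residues[sp] for sp in group]
    counts: dict[str, int] = {}
    for r in observed:
        if r != "-":
            counts[r] = counts.get(r, 0) + 1
    if not counts:
        return 0.0
    consensus = min(sorted(counts), key=lambda r: (-counts[r], r))
    return counts[consensus] / len(group)
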