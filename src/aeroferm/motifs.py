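"""Promoter extraction and degenerate-consensus binding-site counting.

A putative promoter is the fixed window (default 1 kb) immediately upstream of
a gene's coding sequence, strand-aware.  Binding sites are exact matches to an
IUPAC degenerate consensus; the default is the Gal4p upstream activating
sequence CGG-N11-CCG, written ``CGGN{11}CCG``.  That consensus is its own
reverse complement, so a single forward scan sees every genomic site; for
non-palindromic motifs both strands can be scanned with de-duplication of
offsets that describe the same genomic window.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MOTIF = "CGGN{11}CCG"
DEFAULT_UPSTREAM = 1000


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IupacMotif:
    """A degenerate consensus as an expanded IUPAC string plus per-position base sets."""

    pattern: str
    base_sets: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def fixed_positions(self) -> tuple[int, ...]:
        """Positions with exactly one allowed base (the non-degenerate core)."""
        return tuple(i for i, s in enumerate(self.base_sets) if len(s) == 1)

    def regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all found
        body = "".join("[" + "".join(sorted(s)) + "]" for s in self.base_sets)
        return re.compile(f"(?=({body}))")


def parse_motif(text: str) -> IupacMotif:
    """Parse an IUPAC consensus with optional run-length shorthand ``X{k}``.

    ``CGGN{11}CCG`` expands to a 17-position motif.  Invalid codes and
    malformed run-lengths are reported with their position in the input.
    """
    expanded: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i].upper()
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {text[i]!r} at position {i}")
        i += 1
        reps = 1
        if i < len(text) and text[i] == "{":
            m = re.match(r"\{(\d+)\}", text[i:])
            if not m:
                raise ValueError(f"malformed run-length at position {i}")
            reps = int(m.group(1))
            i += m.end()
        expanded.extend(ch * reps)
    if not expanded:
        raise ValueError("empty motif")
    pattern = "".join(expanded)
    return IupacMotif(pattern=pattern, base_sets=tuple(IUPAC[c] for c in pattern))


def complement_motif(motif: IupacMotif) -> IupacMotif:
    """The motif matching the reverse complement of the original's matches."""
    rc_sets = tuple(
        frozenset(b.translate(_COMPLEMENT) for b in s) for s in reversed(motif.base_sets)
    )
    inv = {v: k for k, v in IUPAC.items()}
    return IupacMotif(pattern="".join(inv[s] for s in rc_sets), base_sets=rc_sets)


def is_self_reverse_complement(motif: IupacMotif) -> bool:
    """True when the motif equals its own reverse complement position-by-position.

    For such motifs (the default Gal4p consensus is one) every reverse-strand
    match is also a forward-strand match, so scanning one strand suffices.
    """
    return complement_motif(motif).base_sets == motif.base_sets


@dataclass(frozen=True)
class MotifHits:
    """Match offsets (0-based, strictly increasing) within one promoter."""

    gene: str
    offsets: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.offsets)


def count_sites(
    sequence: str,
    motif: IupacMotif,
    strands: str = "forward",
    gene: str = "",
) -> MotifHits:
    """All (possibly overlapping) exact consensus matches in a promoter.

    ``strands="both"`` additionally scans the reverse complement and reports
    each distinct genomic window once, as the offset of its leftmost base on
    the given sequence.  Ambiguous ``N`` bases in the sequence never match.
    A sequence shorter than the motif simply has zero hits.
    """
    if strands not in {"forward", "both"}:
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    seq = sequence.upper()
    offsets = {m.start() for m in motif.regex().finditer(seq)}
    if strands == "both":
        # a reverse-strand site at genomic offset o matches the complement motif
        # read on the forward sequence at the same offset
        offsets |= {m.start() for m in complement_motif(motif).regex().finditer(seq)}
    return MotifHits(gene=gene, offsets=tuple(sorted(offsets)))


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene's coding span in GFF3 coordinates (1-based, inclusive)."""

    gene: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"gene {self.gene}: invalid coordinates {self.start}..{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene}: strand must be + or -")


@dataclass(frozen=True)
class Promoter:
    """Extracted upstream window, already oriented 5'->3' of the gene."""

    gene: str
    sequence: str
    contig: str
    start: int  # 1-based inclusive genomic start of the window
    end: int    # 1-based inclusive genomic end
    strand: str
    requested_length: int

    @property
    def actual_length(self) -> int:
        return len(self.sequence)

    @property
    def truncated(self) -> bool:
        return self.actual_length < self.requested_length


def gene_models_from_gff(path: str | Path, feature: str = "CDS") -> list[GeneModel]:
    """Gene coding spans from GFF3, one span per gene.

    ``feature`` selects which records anchor the promoter (CDS by default to
    match "upstream of the coding sequence"; ``gene`` or ``mRNA`` also work).
    Multi-record features (CDS segments) are grouped by their parent gene where
    a Parent attribute exists, else by their own ID, and reduced to the
    min-start/max-end span.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    spans: dict[str, list] = {}
    for feat in db.features_of_type(feature):
        parents = feat.attributes.get("Parent")
        key = parents[0] if parents else feat.id
        if feat.end < feat.start:
            raise ValueError(f"{path}: feature {feat.id} has end < start")
        spans.setdefault(key, []).append(feat)
    if not spans:
        raise ValueError(f"{path}: no {feature!r} features found")
    models = []
    for key, feats in spans.items():
        strands = {f.strand for f in feats}
        contigs = {f.seqid for f in feats}
        if len(strands) > 1 or len(contigs) > 1:
            raise ValueError(f"{path}: feature group {key} spans strands/contigs")
        models.append(
            GeneModel(
                gene=key,
                contig=feats[0].seqid,
                start=min(f.start for f in feats),
                end=max(f.end for f in feats),
                strand=feats[0].strand,
            )
        )
    return sorted(models, key=lambda g: (g.contig, g.start))


def extract_promoters(
    fasta: str | Path | Mapping[str, str],
    genes: Iterable[GeneModel],
    length: int = DEFAULT_UPSTREAM,
) -> dict[str, Promoter]:
    """Strand-aware upstream windows for each gene.

    For a + strand gene the window is the ``length`` bases ending just before
    its start; for a - strand gene, the bases just after its end, reverse
    complemented.  Windows are truncated (and flagged) at contig edges, never
    padded.  Overlap with neighboring genes is intentionally ignored: the
    window is a flat ``length`` bp regardless of the surrounding annotation.
    """
    if isinstance(fasta, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(fasta), sequence_always_upper=True)
        contigs = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        contigs = {k: v.upper() for k, v in fasta.items()}
    out: dict[str, Promoter] = {}
    for g in genes:
        if g.contig not in contigs:
            raise ValueError(f"gene {g.gene}: contig {g.contig} not in FASTA")
        contig_seq = contigs[g.contig]
        clen = len(contig_seq)
        if g.end > clen:
            raise ValueError(f"gene {g.gene}: coordinates exceed contig length {clen}")
        if g.strand == "+":
            w_start = max(1, g.start - length)
            w_end = g.start - 1
            seq = contig_seq[w_start - 1 : w_end]
        else:
            w_start = g.end + 1
            w_end = min(clen, g.end + length)
            seq = reverse_complement(contig_seq[w_start - 1 : w_end])
        if w_end < w_start:  # gene starts at the very contig edge
            w_start, w_end, seq = g.start, g.start - 1, ""
        promoter = Promoter(
            gene=g.gene, sequence=seq, contig=g.contig,
            start=w_start, end=w_end, strand=g.strand, requested_length=length,
        )
        if promoter.truncated:
            logger.info("gene %s: promoter truncated to %d bp at contig edge",
                        g.gene, promoter.actual_length)
        out[g.gene] = promoter
    return out


def write_promoter_fasta(promoters: Mapping[str, Promoter], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene in sorted(promoters):
            p = promoters[gene]
            fh.write(
                f">{gene} {p.contig}:{p.start}-{p.end}({p.strand})"
                f" truncated={str(p.truncated).lower()}\n"
            )
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# summaries and ablation
# ---------------------------------------------------------------------------


def summarize_by_family(
    hits: Mapping[str, MotifHits],
    family_map: Mapping[str, str],
    species_map: Mapping[str, str],
) -> pd.DataFrame:
    """Species x family matrix of the maximum site count over family members.

    When a species carries several orthologs of a family, the member with the
    most sites represents the family.  Genes with no promoter/hit record are
    logged and contribute nothing.
    """
    records = []
    for gene, family in family_map.items():
        if gene not in hits:
            logger.info("gene %s has no promoter hits record; skipped", gene)
            continue
        if gene not in species_map:
            raise ValueError(f"gene {gene} has no species assignment")
        records.append({"species": species_map[gene], "family": family,
                        "count": hits[gene].count})
    if not records:
        return pd.DataFrame()
    df = pd.DataFrame(records)
    return (
        df.pivot_table(index="species", columns="family", values="count", aggfunc="max")
        .astype("Int64")
    )


def ablate_sites(
    sequence: str,
    motif: IupacMotif,
    seed: int,
    hits: MotifHits | None = None,
    max_rounds: int = 10,
) -> tuple[str, int]:
    """Mutate binding sites until a both-strand re-scan finds zero matches.

    Within each match, substitutions are made only at the motif's
    non-degenerate positions (the CGG/CCG triplets of the default consensus),
    one base per match per round, chosen deterministically from ``seed``; if an
    edit leaves or creates a match, further rounds escalate.  Returns the
    mutated sequence and the number of edited positions.
    """
    if not motif.fixed_positions:
        raise ValueError("motif has no non-degenerate positions to mutate")
    rng = np.random.default_rng(seed)
    seq = list(sequence.upper())
    if hits is not None and hits.offsets:
        expected = count_sites(sequence, motif, strands="both").offsets
        if not set(hits.offsets).issubset(expected):
            raise ValueError("provided hits were not computed on this sequence/motif")
    rc = complement_motif(motif)
    edits = 0
    for _ in range(max_rounds):
        found = [(off, motif) for off in count_sites("".join(seq), motif).offsets]
        found += [(off, rc) for off in count_sites("".join(seq), rc).offsets
                  if (off, motif) not in found]
        # both-strand de-dup: for a palindromic motif the two lists coincide
        seen = set()
        current = []
        for off, m in found:
            if off not in seen:
                seen.add(off)
                current.append((off, m))
        if not current:
            return "".join(seq), edits
        for off, m in current:
            pos = int(rng.choice(m.fixed_positions))
            allowed = m.base_sets[pos]
            choices = sorted(set("ACGT") - allowed)
            seq[off + pos] = str(rng.choice(choices))
            edits += 1
    raise ValueError(f"could not ablate all sites within {max_rounds} rounds")


def write_itol_site_counts(
    summary: pd.DataFrame, path: str | Path, dataset_label: str = "Gal4p sites"
) -> None:
    """Export the per-species maximum site count per family as an iTOL
    multi-value bar annotation."""
    families = list(summary.columns)
    lines = [
        "DATASET_MULTIBAR",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{dataset_label}",
        "FIELD_LABELS\t" + "\t".join(str(f) for f in families),
        "DATA",
    ]
    for species, row in summary.iterrows():
        vals = ["0" if pd.isna(v) else str(int(v)) for v in row]
        lines.append(str(species) + "\t" + "\t".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")
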