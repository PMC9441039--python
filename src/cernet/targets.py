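"""miRNA target prediction by canonical seed matching.

A miRNA represses a transcript through Watson-Crick pairing between the
miRNA seed (nucleotides 2-8 from the 5' end) and a complementary site on the
transcript.  The canonical site grammar, in decreasing strength:

  8mer      perfect match to seed positions 2-8 plus an A opposite position 1
  7mer-m8   perfect match to positions 2-8
  7mer-A1   perfect match to positions 2-7 plus the position-1 A
  6mer      perfect match to positions 2-7 only

Patterns are emitted in DNA alphabet and matched on the sense strand of the
transcript sequence; G:U wobble pairs are not allowed.  Full transcript
sequences are scanned by default (lncRNAs have no 3' UTR annotation); pass
explicit intervals to restrict the scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")  # ascending strength
_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

_RNA = set("ACGU")
_DNA = set("ACGT")


@dataclass(frozen=True)
class SeedMatch:
    """One seed-complementary site, 1-based inclusive on the sense strand."""

    mirna_id: str
    transcript_id: str
    site_type: str
    start: int
    end: int


@dataclass(frozen=True)
class TargetInteraction:
    mirna_id: str
    transcript_id: str
    n_sites: int
    best_site_type: str
    sites: tuple[SeedMatch, ...] = ()


def _norm_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def seed_patterns(mirna_seq: str) -> dict[str, str]:
    """Map each site type to the DNA pattern it requires on the target.

    The target site is the reverse complement of the seed read 3'->5' on the
    miRNA, i.e. revcomp(nt 2-7) for a 6mer, revcomp(nt 2-8) for 7mer-m8, each
    optionally followed by the target-site adenine (A1 variants).
    """
    seq = mirna_seq.upper()
    if len(seq) < 8:
        raise ValueError(f"miRNA too short for seed extraction: {len(seq)} nt")
    if not set(seq) <= _RNA:
        raise ValueError(f"invalid miRNA alphabet in {mirna_seq!r} (expect RNA)")
    seed27 = _norm_dna(seq[1:7])
    seed28 = _norm_dna(seq[1:8])
    rc27 = str(Seq(seed27).reverse_complement())
    rc28 = str(Seq(seed28).reverse_complement())
    return {
        "6mer": rc27,
        "7mer-m8": rc28,
        "7mer-A1": rc27 + "A",
        "8mer": rc28 + "A",
    }


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def find_seed_sites(
    mirna_id: str, mirna_seq: str, transcript_id: str, transcript_seq: str
) -> list[SeedMatch]:
    """All seed sites of one miRNA on one transcript.

    Each position where the 6mer core matches is reported once, classified as
    the strongest site type whose full pattern matches there (8mer > 7mer-m8 >
    7mer-A1 > 6mer).  Coordinates are 1-based inclusive and always span the
    matched pattern.
    """
    pats = seed_patterns(mirna_seq)
    t = _norm_dna(transcript_seq)
    # The 6mer core anchors every site type: 7mer-m8/8mer place it one base
    # later (after the m8 base), 7mer-A1/6mer at the match start.
    best: dict[int, tuple[str, int]] = {}  # core start -> (type, pattern start)
    for site_type in SITE_TYPES:  # ascending strength: later wins
        pat = pats[site_type]
        core_offset = 1 if site_type in ("7mer-m8", "8mer") else 0
        for i in _find_all(t, pat):
            best[i + core_offset] = (site_type, i)
    out = [
        SeedMatch(
            mirna_id=mirna_id,
            transcript_id=transcript_id,
            site_type=site_type,
            start=start + 1,
            end=start + len(pats[site_type]),
        )
        for _, (site_type, start) in sorted(best.items())
    ]
    return out


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    min_site_type: str = "7mer-A1",
) -> list[TargetInteraction]:
    """One TargetInteraction per (miRNA, transcript) pair with a qualifying site.

    ``min_site_type`` gates on site strength; the default excludes bare 6mers,
    which carry little repression signal on their own.
    """
    if min_site_type not in _SITE_RANK:
        raise ValueError(f"unknown site type {min_site_type!r}")
    if len(set(mirnas)) != len(mirnas) or len(set(transcripts)) != len(transcripts):
        raise ValueError("duplicate sequence ids")
    min_rank = _SITE_RANK[min_site_type]
    out: list[TargetInteraction] = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            sites = [
                s
                for s in find_seed_sites(mid, mirnas[mid], tid, transcripts[tid])
                if _SITE_RANK[s.site_type] >= min_rank
            ]
            if sites:
                best = max(sites, key=lambda s: _SITE_RANK[s.site_type])
                out.append(
                    TargetInteraction(
                        mirna_id=mid,
                        transcript_id=tid,
                        n_sites=len(sites),
                        best_site_type=best.site_type,
                        sites=tuple(sites),
                    )
                )
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict (order-preserving)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return records


def write_interactions_tsv(
    interactions: Iterable[TargetInteraction], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\ttranscript_id\tn_sites\tbest_site_type\tsites\n")
        for it in interactions:
            joined = ";".join(f"{s.start}:{s.end}:{s.site_type}" for s in it.sites)
            fh.write(
                f"{it.mirna_id}\t{it.transcript_id}\t{it.n_sites}"
                f"\t{it.best_site_type}\t{joined}\n"
            )
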