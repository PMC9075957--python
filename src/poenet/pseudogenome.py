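"""Strain pseudo-genome construction and annotation liftover.

Builds a strain-specific genome by substituting SNVs and applying indels
from a variant set onto a reference, and lifts annotation coordinates across
the indel-induced indexing differences: every feature is shifted by the
cumulative length change of all indels strictly upstream, and features
overlapping a deletion are truncated to the surviving interval (features
entirely inside a deletion are dropped with a warning).

Coordinates are 1-based inclusive throughout (GTF convention).  VCF-style
anchored indels are normalized to pure insert/delete events before
application, all variants are applied against original reference
coordinates in one pass, and overlapping variants are illegal.  Only
homozygous alternative calls are consumed — the target is an inbred-strain
consensus genome, not a phased diploid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_variants",
    "apply_variants",
    "liftover_annotations",
    "invert_variants",
    "PseudoGenome",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "read_gtf",
    "write_gtf",
]


@dataclass
class _Event:
    """A normalized edit in reference coordinates.

    kind "sub": replace [pos, pos+len(seq)-1] with seq (no length change).
    kind "ins": insert seq after position pos (anchor).
    kind "del": delete [pos, pos+length-1].
    """

    kind: str
    pos: int
    seq: str = ""
    length: int = 0

    @property
    def ref_span(self):
        if self.kind == "sub":
            return self.pos, self.pos + len(self.seq) - 1
        if self.kind == "del":
            return self.pos, self.pos + self.length - 1
        return self.pos, self.pos  # insertion occupies its anchor base

    @property
    def delta(self) -> int:
        return {"sub": 0, "ins": len(self.seq), "del": -self.length}[self.kind]


@dataclass
class PseudoGenome:
    """Variant-substituted sequences plus the per-chromosome edit events."""

    sequences: dict
    events: dict = field(default_factory=dict)

    def offset_table(self) -> pd.DataFrame:
        """Cumulative length change downstream of each indel."""
        rows = []
        for chrom, events in self.events.items():
            cum = 0
            for ev in events:
                if ev.delta == 0:
                    continue
                cum += ev.delta
                rows.append(
                    {"chrom": chrom, "ref_pos": ev.ref_span[1], "cumulative_offset": cum}
                )
        return pd.DataFrame(rows, columns=["chrom", "ref_pos", "cumulative_offset"])

    def map_position(self, chrom: str, pos: int):
        """Map a 1-based reference position to the pseudo-genome.

        Returns (new_pos, "ok") or, when the position falls inside a
        deletion, (None, "deleted").
        """
        shift = 0
        for ev in self.events.get(chrom, ()):
            lo, hi = ev.ref_span
            if ev.kind == "ins":
                if pos > ev.pos:
                    shift += ev.delta
            elif ev.kind == "del":
                if lo <= pos <= hi:
                    return None, "deleted"
                if pos > hi:
                    shift += ev.delta
        return pos + shift, "ok"


def normalize_variants(variants: pd.DataFrame, reference: dict) -> dict:
    """Validate a VariantSet and normalize records to pure edit events.

    ``variants`` has columns chrom, pos (1-based), ref, alt.  Records must
    be sorted by (chrom, pos), non-overlapping on the reference, and their
    ref allele must match the reference sequence.  Anchored indels (alt a
    prefix of ref, or ref a prefix of alt) become pure delete/insert events;
    equal-length records are substitutions.
    """
    events: dict = {}
    seen_end: dict = {}
    df = variants.sort_values(["chrom", "pos"], kind="mergesort")
    if not (df.index == variants.index).all():
        raise ValueError("variant records must be sorted by (chrom, pos)")
    for rec in variants.itertuples(index=False):
        chrom, pos, ref, alt = str(rec.chrom), int(rec.pos), str(rec.ref), str(rec.alt)
        if chrom not in reference:
            raise ValueError(f"variant on unknown chromosome {chrom!r}")
        seq = reference[chrom]
        if seq[pos - 1 : pos - 1 + len(ref)] != ref:
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: expected {ref!r}, "
                f"found {seq[pos - 1: pos - 1 + len(ref)]!r}"
            )
        if len(ref) == len(alt):
            ev = _Event("sub", pos, seq=alt)
        elif len(alt) > len(ref) and alt.startswith(ref):
            ev = _Event("ins", pos + len(ref) - 1, seq=alt[len(ref):])
        elif len(ref) > len(alt) and ref.startswith(alt):
            ev = _Event("del", pos + len(alt), length=len(ref) - len(alt))
        else:
            raise ValueError(
                f"unsupported complex variant at {chrom}:{pos} ({ref}>{alt}); "
                "normalize to SNV/MNV or anchored indel first"
            )
        lo, hi = pos, pos + len(ref) - 1
        if chrom in seen_end and lo <= seen_end[chrom]:
            raise ValueError(f"overlapping variants on {chrom} at position {pos}")
        seen_end[chrom] = hi
        events.setdefault(chrom, []).append(ev)
    return events


def apply_variants(reference: dict, variants: pd.DataFrame) -> PseudoGenome:
    """Build the strain sequence: SNVs in place, indels left-to-right.

    Output length per chromosome is input length + sum(len(alt) - len(ref)).
    """
    events = normalize_variants(variants, reference)
    sequences = {}
    for chrom, seq in reference.items():
        evs = events.get(chrom, [])
        pieces = []
        cursor = 0  # 0-based position in reference
        for ev in evs:
            if ev.kind == "sub":
                pieces.append(seq[cursor : ev.pos - 1])
                pieces.append(ev.seq)
                cursor = ev.pos - 1 + len(ev.seq)
            elif ev.kind == "ins":
                pieces.append(seq[cursor : ev.pos])
                pieces.append(ev.seq)
                cursor = ev.pos
            else:  # deletion
                pieces.append(seq[cursor : ev.pos - 1])
                cursor = ev.pos - 1 + ev.length
        pieces.append(seq[cursor:])
        sequences[chrom] = "".join(pieces)
    return PseudoGenome(sequences=sequences, events=events)


def liftover_annotations(features: pd.DataFrame, genome: PseudoGenome) -> pd.DataFrame:
    """Shift feature coordinates across indel offsets.

    ``features`` needs chrom/start/end columns (1-based inclusive); other
    columns pass through.  Starts or ends inside a deletion are truncated to
    the surviving interval; features entirely within a deletion are dropped
    with a logged warning.
    """
    rows = []
    for idx, feat in features.iterrows():
        chrom = str(feat["chrom"])
        start, end = int(feat["start"]), int(feat["end"])
        new_start, s_status = genome.map_position(chrom, start)
        new_end, e_status = genome.map_position(chrom, end)
        if s_status == "deleted" and e_status == "deleted":
            # both ends may sit in different deletions with survivors between
            interior = [
                genome.map_position(chrom, p)[0]
                for p in range(start, end + 1)
                if genome.map_position(chrom, p)[1] == "ok"
            ]
            if not interior:
                logger.warning(
                    "feature %s at %s:%d-%d lies entirely inside a deletion; dropped",
                    idx, chrom, start, end,
                )
                continue
            new_start, new_end = interior[0], interior[-1]
        elif s_status == "deleted":
            p = start
            while genome.map_position(chrom, p)[1] == "deleted":
                p += 1
            new_start = genome.map_position(chrom, p)[0]
        elif e_status == "deleted":
            p = end
            while genome.map_position(chrom, p)[1] == "deleted":
                p -= 1
            new_end = genome.map_position(chrom, p)[0]
        row = feat.copy()
        row["start"], row["end"] = new_start, new_end
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True) if rows else features.iloc[0:0].copy()


def invert_variants(variants: pd.DataFrame, reference: dict) -> pd.DataFrame:
    """Variant set that undoes ``variants`` when applied to the pseudo-genome.

    Positions are re-expressed in pseudo-genome coordinates; applying the
    result to the pseudo-genome restores the reference exactly.
    """
    genome = apply_variants(reference, variants)
    rows = []
    for rec in variants.itertuples(index=False):
        chrom, pos, ref, alt = str(rec.chrom), int(rec.pos), str(rec.ref), str(rec.alt)
        if len(ref) == len(alt):
            new_pos, _ = genome.map_position(chrom, pos)
        else:
            # anchor base survives both insertions and deletions
            new_pos, _ = genome.map_position(chrom, pos)
        rows.append({"chrom": chrom, "pos": new_pos, "ref": alt, "alt": ref})
    return pd.DataFrame(rows).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# file formats


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_vcf(path) -> pd.DataFrame:
    """Homozygous-alt variant records from a VCF (text or bgzipped).

    Heterozygous genotype calls are rejected (skipped with a warning): the
    target is an inbred-strain consensus.  Multi-allelic records take the
    first ALT only when the genotype is homozygous for it.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                continue
            if rec.samples:
                gt = rec.samples[0].get("GT")
                if gt is None or len(set(gt)) != 1 or gt[0] in (None, 0):
                    logger.warning(
                        "skipping non-hom-alt record at %s:%d", rec.chrom, rec.pos
                    )
                    continue
                alt = rec.alts[gt[0] - 1]
            rows.append({"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alt})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


GTF_COLUMNS = [
    "chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attribute",
]


def read_gtf(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GTF_COLUMNS,
        dtype={"chrom": str},
    )
    return df


def write_gtf(features: pd.DataFrame, path) -> None:
    out = features.copy()
    for col in GTF_COLUMNS:
        if col not in out.columns:
            out[col] = "."
    out[GTF_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
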