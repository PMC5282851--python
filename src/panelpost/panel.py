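"""Amplicon panel and transcript models.

The panel is the coordinate backbone of the pipeline: every amplicon has a
genomic span plus primer footprints at both ends, and only the primer-free
*insert* carries independent sequencing evidence (primer bases are copied
from the oligo, not the template, so variants seen only under a primer are
artifactual by construction).

Internal coordinates are 1-based inclusive (the VCF convention); BED input
(0-based half-open) is converted at the boundary.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_BASES = "ACGT"


def synthetic_reference(chrom: str, start: int, end: int) -> str:
    """Deterministic pseudo-random bases for the synthetic mini-genome,
    over a 1-based inclusive window; stable across runs and machines
    (CRC-seeded hash of chromosome name and position)."""
    salt = zlib.crc32(chrom.encode())
    pos = np.arange(start, end + 1, dtype=np.uint64)
    vals = (pos * np.uint64(2654435761) + np.uint64(salt)) % np.uint64(4)
    return "".join(_BASES[int(v)] for v in vals)


class PanelFormatError(ValueError):
    """A panel input file is malformed or internally inconsistent."""


@dataclass(frozen=True)
class Amplicon:
    """One PCR amplicon: genomic span, primer footprints, gene assignment.

    ``start``/``end`` are 1-based inclusive and span the whole amplified
    product including both primers.
    """

    name: str
    chrom: str
    start: int
    end: int
    fwd_primer_len: int
    rev_primer_len: int
    gene: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PanelFormatError(
                f"amplicon {self.name}: start {self.start} > end {self.end}"
            )
        if not self.gene:
            raise PanelFormatError(f"amplicon {self.name}: empty gene symbol")
        if self.fwd_primer_len < 0 or self.rev_primer_len < 0:
            raise PanelFormatError(f"amplicon {self.name}: negative primer length")
        if self.fwd_primer_len + self.rev_primer_len >= self.length:
            raise PanelFormatError(
                f"amplicon {self.name}: primers ({self.fwd_primer_len}+"
                f"{self.rev_primer_len} bp) leave no insert in a "
                f"{self.length} bp product"
            )
        if self.strand not in ("+", "-"):
            raise PanelFormatError(f"amplicon {self.name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def insert_start(self) -> int:
        return self.start + self.fwd_primer_len

    @property
    def insert_end(self) -> int:
        return self.end - self.rev_primer_len

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def in_insert(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.insert_start <= pos <= self.insert_end


def insert_region(a: Amplicon) -> tuple[int, int]:
    """Primer-free insert of ``a`` as a 1-based inclusive interval."""
    return a.insert_start, a.insert_end


class PanelDefinition:
    """An ordered collection of amplicons with gene/chromosome bookkeeping."""

    def __init__(self, amplicons: Iterable[Amplicon]):
        self.amplicons: list[Amplicon] = list(amplicons)
        names = [a.name for a in self.amplicons]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise PanelFormatError(f"duplicate amplicon names: {', '.join(dup)}")
        self.chromosome_of: dict[str, str] = {}
        for a in self.amplicons:
            prev = self.chromosome_of.setdefault(a.gene, a.chrom)
            if prev != a.chrom:
                raise PanelFormatError(
                    f"gene {a.gene} assigned to both {prev} and {a.chrom}"
                )

    @property
    def genes(self) -> set[str]:
        return set(self.chromosome_of)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons)

    def amplicons_of_gene(self, gene: str) -> list[Amplicon]:
        return [a for a in self.amplicons if a.gene == gene]

    def covering(self, chrom: str, pos: int) -> list[Amplicon]:
        """All amplicons whose full product (primers included) covers a locus."""
        return [a for a in self.amplicons if a.contains(chrom, pos)]

    def in_any_insert(self, chrom: str, pos: int) -> bool:
        return any(a.in_insert(chrom, pos) for a in self.amplicons)

    def genes_on_chromosome(self, chrom: str) -> set[str]:
        return {g for g, c in self.chromosome_of.items() if c == chrom}


def load_panel(bed_path: str | Path, manifest_path: str | Path) -> PanelDefinition:
    """Load a panel from a BED file of amplicon spans plus a manifest TSV.

    The BED is 0-based half-open with the amplicon name in column 4; the
    manifest carries columns ``name``, ``gene``, ``fwd_primer_len``,
    ``rev_primer_len`` and optionally ``strand``. Coordinates are converted
    to the internal 1-based inclusive convention.
    """
    bed = pd.read_csv(
        bed_path,
        sep=r"\s+",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start0", "end0", "name"],
        dtype={"chrom": str, "start0": int, "end0": int, "name": str},
    )
    manifest = pd.read_csv(manifest_path, sep="\t", dtype={"name": str, "gene": str})
    required = {"name", "gene", "fwd_primer_len", "rev_primer_len"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise PanelFormatError(f"manifest missing columns: {sorted(missing_cols)}")
    rows = manifest.set_index("name", verify_integrity=True)

    amplicons = []
    for rec in bed.itertuples(index=False):
        if rec.name not in rows.index:
            raise PanelFormatError(f"no manifest row for BED amplicon {rec.name!r}")
        m = rows.loc[rec.name]
        amplicons.append(
            Amplicon(
                name=rec.name,
                chrom=rec.chrom,
                start=rec.start0 + 1,  # BED 0-based -> 1-based inclusive
                end=rec.end0,
                fwd_primer_len=int(m["fwd_primer_len"]),
                rev_primer_len=int(m["rev_primer_len"]),
                gene=str(m["gene"]),
                strand=str(m.get("strand", "+")) if "strand" in m else "+",
            )
        )
    return PanelDefinition(amplicons)


def write_panel(
    panel: PanelDefinition, bed_path: str | Path, manifest_path: str | Path
) -> None:
    """Write a panel back to BED + manifest; round-trips with :func:`load_panel`."""
    with open(bed_path, "w") as bed:
        for a in panel:
            bed.write(f"{a.chrom}\t{a.start - 1}\t{a.end}\t{a.name}\n")
    pd.DataFrame(
        {
            "name": [a.name for a in panel],
            "gene": [a.gene for a in panel],
            "fwd_primer_len": [a.fwd_primer_len for a in panel],
            "rev_primer_len": [a.rev_primer_len for a in panel],
            "strand": [a.strand for a in panel],
        }
    ).to_csv(manifest_path, sep="\t", index=False)


@dataclass
class TranscriptModel:
    """Spliced coding model of one gene.

    ``cds_intervals`` are 1-based inclusive genomic intervals in genomic
    order; ``sequence`` is the spliced, strand-oriented coding sequence
    (already reverse-complemented for minus-strand genes).
    """

    gene: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    sequence: str
    protein_accession: str = ""
    partial: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0:
            self.partial = True
        if not self.partial and not self.sequence.upper().startswith("ATG"):
            self.partial = True

    @property
    def cds_length(self) -> int:
        return len(self.sequence)

    def protein(self) -> str:
        return str(Seq(self.sequence).translate())

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a genomic position to a 1-based CDS coordinate, or None."""
        offset = 0
        if self.strand == "+":
            for lo, hi in self.cds_intervals:
                if lo <= pos <= hi:
                    return offset + (pos - lo) + 1
                offset += hi - lo + 1
            return None
        for lo, hi in reversed(self.cds_intervals):
            if lo <= pos <= hi:
                return offset + (hi - pos) + 1
            offset += hi - lo + 1
        return None


def load_transcripts(
    gff_path: str | Path, fasta_path: str | Path
) -> dict[str, TranscriptModel]:
    """Build per-gene transcript models from GFF3-subset CDS features + FASTA.

    Only ``CDS`` features are read; attributes must carry ``gene=`` and may
    carry ``protein_id=``. Minus-strand models are spliced in genomic order
    then reverse-complemented. A CDS whose length is not divisible by 3 is
    flagged partial with a warning rather than rejected.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    features: dict[str, dict] = {}
    with open(gff_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            seqid, _, _, start, end, _, strand, _, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene = attr.get("gene") or attr.get("Name")
            if gene is None:
                raise PanelFormatError(f"CDS feature without gene attribute: {line}")
            feat = features.setdefault(
                gene,
                {"chrom": seqid, "strand": strand,
                 "protein": attr.get("protein_id", ""), "ivals": []},
            )
            feat["ivals"].append((int(start), int(end)))

    models: dict[str, TranscriptModel] = {}
    for gene, feat in features.items():
        chrom = feat["chrom"]
        if chrom not in seqs:
            raise PanelFormatError(f"gene {gene}: sequence {chrom!r} not in FASTA")
        ref = seqs[chrom]
        ivals = sorted(feat["ivals"])
        spliced = "".join(ref[lo - 1 : hi] for lo, hi in ivals)
        if feat["strand"] == "-":
            spliced = str(Seq(spliced).reverse_complement())
        model = TranscriptModel(
            gene=gene,
            chrom=chrom,
            strand=feat["strand"],
            cds_intervals=ivals,
            sequence=spliced,
            protein_accession=feat["protein"],
        )
        if len(spliced) % 3 != 0:
            warnings.warn(
                f"gene {gene}: CDS length {len(spliced)} not divisible by 3; "
                "flagged partial",
                stacklevel=2,
            )
        models[gene] = model
    return models
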