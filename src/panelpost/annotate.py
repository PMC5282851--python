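"""Codon-aware protein consequence annotation.

Annotates SNVs and short indels against :class:`~panelpost.panel.TranscriptModel`
coding sequences, emitting HGVS-p style descriptions with 3-letter amino
acids. Covers the consequence classes the reporting logic needs
(synonymous, missense, nonsense, frameshift, inframe ins/del/delins); the
full HGVS grammar (extensions, dup, intronic) is out of scope.

The ``expressed`` flag implements haplotype-aware reinterpretation: a
missense co-phased with an upstream frameshift is still present in the
genome but never expressed at the protein level, so it must not be
reported as actionable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .panel import TranscriptModel
from .qc import VariantCall


@dataclass
class AnnotationResult:
    """Protein-level interpretation of one (possibly merged) variant."""

    hgvs_p: str
    effect: str  # synonymous | missense | nonsense | frameshift |
    #              inframe_delins | inframe_del | inframe_ins | non_coding
    expressed: bool = True
    origin: str = "ambiguous"

    @property
    def discard(self) -> bool:
        """Synonymous and non-coding calls are dropped from reports."""
        return self.effect in ("synonymous", "non_coding")


def _aa3(aa: str) -> str:
    return "*" if aa == "*" else seq3(aa)


def _truncate_at_stop(protein: str) -> str:
    i = protein.find("*")
    return protein if i < 0 else protein[: i + 1]


def _cds_span(t: TranscriptModel, v: VariantCall) -> tuple[int, int] | None:
    """1-based CDS coordinates of the variant's reference span, or None."""
    last = v.pos + len(v.ref) - 1
    c1 = t.genomic_to_cds(v.pos)
    c2 = t.genomic_to_cds(last)
    if c1 is None or c2 is None:
        return None
    return (c1, c2) if c1 <= c2 else (c2, c1)


def edited_cds(t: TranscriptModel, v: VariantCall) -> str:
    """Apply a variant to the transcript's coding sequence.

    Strand-aware: on minus-strand transcripts the genomic alleles are
    reverse-complemented before substitution. The reference allele must
    match the transcript sequence over its span.
    """
    span = _cds_span(t, v)
    if span is None:
        raise ValueError(f"variant {v.key} outside CDS of {t.gene}")
    lo, hi = span
    seq = t.sequence
    if t.strand == "+":
        ref, alt = v.ref.upper(), v.alt.upper()
    else:
        ref = str(Seq(v.ref).reverse_complement())
        alt = str(Seq(v.alt).reverse_complement())
    if seq[lo - 1 : hi] != ref:
        raise ValueError(
            f"reference mismatch for {v.key}: transcript has "
            f"{seq[lo - 1:hi]!r}, variant says {ref!r}"
        )
    return seq[: lo - 1] + alt + seq[hi:]


def _protein_diff(p_ref: str, p_alt: str) -> tuple[int, str, str]:
    """Trim shared prefix/suffix; return (0-based start, ref_seg, alt_seg)."""
    n_pre = 0
    limit = min(len(p_ref), len(p_alt))
    while n_pre < limit and p_ref[n_pre] == p_alt[n_pre]:
        n_pre += 1
    n_suf = 0
    while (
        n_suf < limit - n_pre
        and p_ref[len(p_ref) - 1 - n_suf] == p_alt[len(p_alt) - 1 - n_suf]
    ):
        n_suf += 1
    return n_pre, p_ref[n_pre : len(p_ref) - n_suf], p_alt[n_pre : len(p_alt) - n_suf]


def is_frameshift(v: VariantCall) -> bool:
    return (len(v.alt) - len(v.ref)) % 3 != 0


def annotate_protein(
    v: VariantCall,
    t: TranscriptModel,
    phased_context: Sequence[VariantCall] = (),
) -> AnnotationResult:
    """Consequence + HGVS-p for one variant on one transcript.

    ``phased_context`` lists variants known (by read-backed phasing) to lie
    on the same haplotype; an upstream frameshift among them truncates the
    protein before ``v`` and sets ``expressed = False``.
    """
    span = _cds_span(t, v)
    if span is None:
        return AnnotationResult(hgvs_p="p.?", effect="non_coding")

    p_ref = _truncate_at_stop(str(Seq(t.sequence).translate()))
    if is_frameshift(v):
        shifted = edited_cds(t, v)
        usable = shifted[: len(shifted) - len(shifted) % 3]
        p_fs = _truncate_at_stop(str(Seq(usable).translate()))
        n_pre, ref_seg, _ = _protein_diff(p_ref, p_fs)
        if ref_seg:
            first = ref_seg[0]
        else:  # frameshift beyond the compared region
            first = p_ref[min(n_pre, len(p_ref) - 1)]
        hgvs = f"p.{_aa3(first)}{n_pre + 1}fs"
        return AnnotationResult(hgvs_p=hgvs, effect="frameshift",
                                expressed=_expressed(v, t, phased_context))

    p_alt = _truncate_at_stop(str(Seq(edited_cds(t, v)).translate()))
    # stop gain: the truncated-protein diff would otherwise masquerade as
    # an inframe deletion
    if (
        len(v.ref) == len(v.alt)
        and p_alt.endswith("*")
        and len(p_alt) < len(p_ref)
        and p_ref[: len(p_alt) - 1] == p_alt[:-1]
    ):
        k = len(p_alt)
        return AnnotationResult(
            hgvs_p=f"p.{_aa3(p_ref[k - 1])}{k}*", effect="nonsense",
            expressed=_expressed(v, t, phased_context),
        )
    n_pre, ref_seg, alt_seg = _protein_diff(p_ref, p_alt)
    if not ref_seg and not alt_seg:
        c1 = span[0]
        aa_idx = (c1 - 1) // 3
        aa = p_ref[aa_idx] if aa_idx < len(p_ref) else "?"
        hgvs = f"p.{_aa3(aa)}{aa_idx + 1}="
        return AnnotationResult(hgvs_p=hgvs, effect="synonymous")

    start = n_pre + 1  # 1-based protein coordinate of first change
    if len(ref_seg) == 1 and len(alt_seg) == 1:
        effect = "nonsense" if alt_seg == "*" else "missense"
        hgvs = f"p.{_aa3(ref_seg)}{start}{_aa3(alt_seg)}"
    elif ref_seg and not alt_seg:
        effect = "inframe_del"
        end = start + len(ref_seg) - 1
        if len(ref_seg) == 1:
            hgvs = f"p.{_aa3(ref_seg)}{start}del"
        else:
            hgvs = (f"p.{_aa3(ref_seg[0])}{start}_"
                    f"{_aa3(ref_seg[-1])}{end}del")
    elif alt_seg and not ref_seg:
        effect = "inframe_ins"
        left = p_ref[n_pre - 1] if n_pre >= 1 else "?"
        right = p_ref[n_pre] if n_pre < len(p_ref) else "?"
        ins = "".join(_aa3(a) for a in alt_seg)
        hgvs = (f"p.{_aa3(left)}{n_pre}_"
                f"{_aa3(right)}{n_pre + 1}ins{ins}")
    else:
        effect = "inframe_delins"
        end = start + len(ref_seg) - 1
        repl = "".join(_aa3(a) for a in alt_seg)
        if len(ref_seg) == 1:
            hgvs = f"p.{_aa3(ref_seg)}{start}delins{repl}"
        else:
            hgvs = (f"p.{_aa3(ref_seg[0])}{start}_"
                    f"{_aa3(ref_seg[-1])}{end}delins{repl}")
    return AnnotationResult(hgvs_p=hgvs, effect=effect,
                            expressed=_expressed(v, t, phased_context))


def _expressed(
    v: VariantCall, t: TranscriptModel, phased_context: Sequence[VariantCall]
) -> bool:
    """False when a co-phased frameshift lies 5' of ``v`` on the transcript."""
    my_span = _cds_span(t, v)
    if my_span is None:
        return True
    for other in phased_context:
        if other.key == v.key or not is_frameshift(other):
            continue
        other_span = _cds_span(t, other)
        if other_span is not None and other_span[0] < my_span[0]:
            return False
    return True
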