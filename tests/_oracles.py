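"""Independent brute-force oracles used by the property tests.

These deliberately avoid the code paths they check: indel placement is
found by enumerating every position that reproduces the mutant sequence,
and consequences are derived by rebuilding the whole mutant chromosome,
shifting the annotation intervals, and re-extracting the coding sequence.
"""

from __future__ import annotations

from felvar.models import GeneModel, reverse_complement, translate_cds


def enumerate_insertion_placements(genome: str, mutant: str) -> list[int]:
    """All 0-based offsets p such that mutant == genome[:p] + X + genome[p:].

    Returns the anchor positions (number of reference bases before the
    inserted block).  Assumes len(mutant) > len(genome).
    """
    L = len(mutant) - len(genome)
    hits = []
    for p in range(len(genome) + 1):
        if genome[:p] + mutant[p : p + L] + genome[p:] == mutant:
            hits.append(p)
    return hits


def enumerate_deletion_placements(genome: str, mutant: str) -> list[int]:
    """All 0-based start offsets s such that deleting L bases at s gives mutant."""
    L = len(genome) - len(mutant)
    hits = []
    for s in range(len(genome) - L + 1):
        if genome[:s] + genome[s + L :] == mutant:
            hits.append(s)
    return hits


def shifted_gene_intervals(
    gene: GeneModel, edit_pos: int, ref: str, alt: str
) -> list[tuple[int, int]] | None:
    """CDS intervals on the mutant chromosome for a left-aligned indel/SNV.

    ``edit_pos`` is the variant's 1-based anchor position.  Returns None
    when the edit is not strictly inside a single interval (the oracle
    does not handle boundary-spanning edits).
    """
    d = len(alt) - len(ref)
    if d == 0:
        return list(gene.cds_intervals)
    if d > 0:  # insertion after edit_pos
        point = edit_pos
        inside = any(s <= point < e for s, e in gene.cds_intervals)
        if not inside:
            return None
        out = []
        for s, e in gene.cds_intervals:
            if s <= point < e:
                out.append((s, e + d))
            elif s > point:
                out.append((s + d, e + d))
            else:
                out.append((s, e))
        return out
    # deletion of bases edit_pos+1 .. edit_pos+|d|
    del_start, del_end = edit_pos + 1, edit_pos - d
    inside = any(s <= del_start and del_end <= e for s, e in gene.cds_intervals)
    if not inside:
        return None
    out = []
    for s, e in gene.cds_intervals:
        if s <= del_start and del_end <= e:
            out.append((s, e + d))
        elif s > del_end:
            out.append((s + d, e + d))
        elif e < del_start:
            out.append((s, e))
        else:
            return None
    return out


def oracle_consequence(
    genome_seq: str, gene: GeneModel, edit_pos: int, ref: str, alt: str
) -> dict | None:
    """Rebuild the mutant chromosome and re-extract/translate the CDS.

    Returns dict(category, wt_prot, mut_prot) or None when the edit is
    outside the oracle's scope (boundary-spanning).
    """
    intervals = shifted_gene_intervals(gene, edit_pos, ref, alt)
    if intervals is None:
        return None
    mutant = genome_seq[: edit_pos - 1] + alt + genome_seq[edit_pos - 1 + len(ref) :]
    parts = [mutant[s - 1 : e] for s, e in sorted(intervals)]
    mut_cds = "".join(parts)
    if gene.strand == "-":
        mut_cds = reverse_complement(mut_cds)
    wt_prot = gene.protein_cached if hasattr(gene, "protein_cached") else None
    # wild-type from the unedited chromosome
    wt_parts = [genome_seq[s - 1 : e] for s, e in sorted(gene.cds_intervals)]
    wt_cds = "".join(wt_parts)
    if gene.strand == "-":
        wt_cds = reverse_complement(wt_cds)
    wt_prot = translate_cds(wt_cds)
    mut_prot = translate_cds(mut_cds)

    net = len(alt) - len(ref)
    if not mut_prot or mut_prot[0] != "M":
        category = "start_lost"
    elif net % 3 != 0 and len(ref) != len(alt):
        category = "frameshift"
    elif wt_prot == mut_prot:
        category = "synonymous"
    elif len(ref) == len(alt) == 1:
        if len(mut_prot) < len(wt_prot) and wt_prot.startswith(mut_prot):
            category = "stop_gained"
        elif len(mut_prot) > len(wt_prot):
            category = "stop_lost"
        else:
            category = "missense"
    elif len(mut_prot) < len(wt_prot) - abs(net) // 3:
        category = "stop_gained"
    elif net > 0:
        category = "inframe_insertion"
    else:
        category = "inframe_deletion"
    return {"category": category, "wt_prot": wt_prot, "mut_prot": mut_prot}


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


def oracle_hgvs_p(wt: str, mut: str, category: str) -> str | None:
    """Protein HGVS for the simple categories; None where not modeled."""
    if category == "synonymous":
        return "p.(=)"
    i = 0
    while i < len(wt) and i < len(mut) and wt[i] == mut[i]:
        i += 1
    if category == "missense":
        return f"p.({_AA3[wt[i]]}{i + 1}{_AA3[mut[i]]})"
    if category == "stop_gained" and len(wt) > len(mut) == i:
        return f"p.({_AA3[wt[i]]}{i + 1}*)"
    if category == "frameshift":
        if i >= len(wt):
            return None  # extension through the wild-type stop
        if i >= len(mut):
            return f"p.({_AA3[wt[i]]}{i + 1}*)"
        return f"p.({_AA3[wt[i]]}{i + 1}{_AA3[mut[i]]}fs*{len(mut) - i + 1})"
    return None
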