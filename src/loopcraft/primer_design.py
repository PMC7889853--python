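"""Mutagenic primer design: QuikChange pairs with Gibson/overlap fallback.

QuikChange-style whole-plasmid mutagenesis uses a pair of fully
complementary primers carrying the edit flanked by template-matching arms;
it works for point mutations and short InDels.  Larger edits fall back to
two-amplicon overlap PCR whose junction primers carry the edit and share an
exact overlap for isothermal (Gibson) assembly.

Melting temperatures follow the QuikChange-manual formula

    Tm = 81.5 + 0.41 * %GC - 675/N - %mismatch

with %mismatch = 0 and N counting only template-matching bases for InDels.
The in-silico mutagenesis simulator at the bottom is deliberately ignorant
of how primers were constructed: it locates annealing arms by maximal
string match on the template, so product-identity tests are
convention-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import DesignError, LoopcraftError
from .variant_model import CdsEdit

__all__ = [
    "PrimerParams",
    "Primer",
    "PrimerPair",
    "GibsonDesign",
    "quikchange_tm",
    "design_quikchange",
    "design_nnk_quikchange",
    "design_gibson_overlap",
    "simulate_quikchange",
    "simulate_pcr",
    "assemble_gibson",
    "simulate_gibson_mutagenesis",
]


@dataclass(frozen=True)
class PrimerParams:
    """Tunable design constraints (QuikChange-manual defaults)."""

    tm_min: float = 78.0  # °C, QuikChange pair
    tm_anneal: float = 55.0  # °C, Gibson/overlap annealing arms
    min_flank: int = 10  # nt of template match on each side of the edit
    max_len: int = 60  # nt, QuikChange primer cap
    max_quikchange_edit: int = 18  # nt (replaced + inserted) before fallback
    overlap: int = 25  # nt of exact junction overlap for Gibson


def _gc_value(base: str) -> float:
    if base in "GC":
        return 1.0
    if base in "AT":
        return 0.0
    if base in "NK":  # degenerate saturation positions count half
        return 0.5
    raise DesignError(f"illegal base {base!r} in primer")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def quikchange_tm(seq: str, n_matching: int | None = None, n_mismatch: int = 0) -> float:
    """QuikChange Tm; ``n_matching`` restricts N (and the GC percentage) to
    template-matching bases, as the manual prescribes for InDel primers."""
    if not seq:
        raise DesignError("empty primer")
    if n_matching is None:
        n = len(seq)
        gc = sum(_gc_value(b) for b in seq)
    else:
        n = n_matching
        # GC share of the matching bases, approximated by the primer-wide
        # GC fraction scaled to the matching length
        gc = sum(_gc_value(b) for b in seq) * n / len(seq)
    if n <= 0:
        raise DesignError("primer has no template-matching bases")
    pct_gc = 100.0 * gc / n
    pct_mismatch = 100.0 * n_mismatch / n
    return 81.5 + 0.41 * pct_gc - 675.0 / n - pct_mismatch


@dataclass(frozen=True)
class Primer:
    """A single oligo (5'->3') with its design bookkeeping."""

    name: str
    sequence: str
    role: str  # forward | reverse | outer_* | junction_*
    tm: float
    matching: int  # template-matching nt entering the Tm

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        return sum(_gc_value(b) for b in self.sequence) / len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """One mutagenic primer pair (or one amplicon's pair in a Gibson design)."""

    variant_name: str
    method: str  # quikchange | gibson_overlap
    forward: Primer
    reverse: Primer


def _grow_flanks(cds: str, edit: CdsEdit, params: PrimerParams, is_sub: bool) -> tuple[int, int]:
    """Symmetric flank growth (ties grow left) until Tm and min_flank hold."""
    left = right = params.min_flank
    while True:
        lo = edit.start - left
        hi = edit.start + len(edit.deleted) + right
        if lo < 0 or hi > len(cds):
            raise DesignError(
                f"edit at {edit.start} too close to the context edge for "
                f"flanks of {left}/{right} nt"
            )
        primer = cds[lo : edit.start] + edit.inserted + cds[edit.start + len(edit.deleted) : hi]
        if len(primer) > params.max_len:
            raise DesignError(
                f"cannot reach Tm >= {params.tm_min} within {params.max_len} nt; "
                "use design_gibson_overlap"
            )
        if is_sub:
            tm = quikchange_tm(primer, n_mismatch=len(edit.inserted))
        else:
            tm = quikchange_tm(primer, n_matching=left + right)
        if tm >= params.tm_min:
            return left, right
        if left <= right:
            left += 1
        else:
            right += 1


def design_quikchange(
    cds: str,
    edit: CdsEdit,
    variant_name: str,
    params: PrimerParams = PrimerParams(),
) -> PrimerPair:
    """Complementary mutagenic primer pair for a small codon-level edit.

    The forward primer is [left flank][edited segment][right flank] on the
    coding strand; the reverse primer is its exact reverse complement.
    Raises :class:`DesignError` (suggesting the Gibson route) for edits
    above ``params.max_quikchange_edit`` or primers that cannot reach Tm.
    """
    if edit.size > params.max_quikchange_edit:
        raise DesignError(
            f"{variant_name}: edit of {edit.size} nt exceeds the QuikChange "
            f"limit of {params.max_quikchange_edit} nt; use design_gibson_overlap"
        )
    is_sub = len(edit.deleted) == len(edit.inserted) and len(edit.deleted) > 0
    left, right = _grow_flanks(cds, edit, params, is_sub)
    lo = edit.start - left
    hi = edit.start + len(edit.deleted) + right
    fwd_seq = cds[lo : edit.start] + edit.inserted + cds[edit.start + len(edit.deleted) : hi]
    if is_sub:
        tm = quikchange_tm(fwd_seq, n_mismatch=len(edit.inserted))
        matching = len(fwd_seq)
    else:
        tm = quikchange_tm(fwd_seq, n_matching=left + right)
        matching = left + right
    fwd = Primer(f"{variant_name}_F", fwd_seq, "forward", tm, matching)
    rev = Primer(f"{variant_name}_R", _revcomp(fwd_seq), "reverse", tm, matching)
    return PrimerPair(variant_name=variant_name, method="quikchange", forward=fwd, reverse=rev)


def design_nnk_quikchange(
    cds: str,
    codon_start: int,
    variant_name: str,
    scheme: str = "NNK",
    params: PrimerParams = PrimerParams(),
) -> PrimerPair:
    """Site-saturation primer with a literal degenerate codon (NNK/NNS) at
    0-based ``codon_start``; degenerate bases contribute 50% GC to the Tm."""
    if scheme not in {"NNK", "NNS"}:
        raise DesignError(f"unsupported scheme {scheme!r}")
    edit = CdsEdit(start=codon_start, deleted=cds[codon_start : codon_start + 3], inserted=scheme)
    return design_quikchange(cds, edit, variant_name, params)


# ---------------------------------------------------------------------------
# Gibson / overlap PCR


@dataclass(frozen=True)
class GibsonDesign:
    variant_name: str
    pairs: tuple[PrimerPair, PrimerPair]
    overlap: int


def _anneal_len(cds: str, pos: int, direction: int, tm_target: float) -> int:
    """Smallest arm length from ``pos`` (rightwards if direction>0, else
    leftwards) whose stand-alone Tm reaches ``tm_target``."""
    n = 12
    while True:
        arm = cds[pos : pos + n] if direction > 0 else cds[max(0, pos - n) : pos]
        if len(arm) < n:
            raise DesignError("context too short for the required annealing arm")
        if quikchange_tm(arm) >= tm_target:
            return n
        n += 1


def design_gibson_overlap(
    cds: str,
    edit: CdsEdit,
    variant_name: str,
    params: PrimerParams = PrimerParams(),
) -> GibsonDesign:
    """Two-amplicon overlap design whose junction primers carry the edit.

    The junction primers share an exact ``params.overlap`` nt window of the
    mutant sequence spanning the edit (grown when the edit itself is
    longer); their 3' arms anneal to the wild-type template at
    >= ``params.tm_anneal``.  The outer primers bracket the supplied
    context, so the assembled product reconstructs the full edited context.
    """
    mutant = edit.apply(cds)
    e0 = edit.start
    e1 = edit.start + len(edit.inserted)  # edit span on the mutant
    ov = max(params.overlap, (e1 - e0) + 6)
    pad = (ov - (e1 - e0)) // 2
    a = e0 - pad
    b = a + ov
    try:
        left_arm = _anneal_len(cds, e0, -1, params.tm_anneal)
    except DesignError as exc:
        raise DesignError(
            f"{variant_name}: edit starts {e0} nt into the context; not enough "
            "upstream sequence for the junction annealing arm"
        ) from exc
    right_arm = _anneal_len(cds, e0 + len(edit.deleted), +1, params.tm_anneal)
    jr_start = min(a, e0 - left_arm)
    jf_end = max(b, e1 + right_arm)
    if jr_start < 1:
        raise DesignError(
            f"{variant_name}: edit starts {e0} nt into the context; not enough "
            f"upstream sequence for a {ov} nt junction overlap"
        )
    if jf_end > len(mutant) - 1:
        raise DesignError(f"{variant_name}: context too short downstream of the edit")

    outer_fwd_len = _anneal_len(cds, 0, +1, params.tm_anneal)
    outer_rev_len = _anneal_len(cds, len(cds), -1, params.tm_anneal)
    outer_fwd = Primer(
        f"{variant_name}_outer_F", cds[:outer_fwd_len], "outer_forward",
        quikchange_tm(cds[:outer_fwd_len]), outer_fwd_len,
    )
    outer_rev = Primer(
        f"{variant_name}_outer_R", _revcomp(cds[-outer_rev_len:]), "outer_reverse",
        quikchange_tm(cds[-outer_rev_len:]), outer_rev_len,
    )
    junction_rev = Primer(
        f"{variant_name}_junction_R", _revcomp(mutant[jr_start:b]), "junction_reverse",
        quikchange_tm(cds[jr_start:e0]), e0 - jr_start,
    )
    junction_fwd = Primer(
        f"{variant_name}_junction_F", mutant[a:jf_end], "junction_forward",
        quikchange_tm(mutant[e1:jf_end]), jf_end - e1,
    )
    pair1 = PrimerPair(variant_name, "gibson_overlap", outer_fwd, junction_rev)
    pair2 = PrimerPair(variant_name, "gibson_overlap", junction_fwd, outer_rev)
    return GibsonDesign(variant_name=variant_name, pairs=(pair1, pair2), overlap=ov)


# ---------------------------------------------------------------------------
# In-silico mutagenesis oracle (construction-blind: maximal string match)


def _seed_sites(template: str, seed: str) -> list[int]:
    sites, i = [], template.find(seed)
    while i >= 0:
        sites.append(i)
        i = template.find(seed, i + 1)
    return sites


def _best_prefix_site(template: str, primer: str, min_len: int = 8) -> tuple[int, int]:
    """(template position, match length) maximising the primer-prefix match.

    Every occurrence of the ``min_len`` seed is extended rightwards; the
    longest extension wins (ties: leftmost), which pins the true annealing
    site even when short spurious seed matches exist elsewhere.
    """
    best: tuple[int, int] | None = None
    for pos in _seed_sites(template, primer[:min_len]):
        n = min_len
        while n < len(primer) and pos + n < len(template) and template[pos + n] == primer[n]:
            n += 1
        if best is None or n > best[1]:
            best = (pos, n)
    if best is None:
        raise LoopcraftError("primer 5' arm does not anneal to the template")
    return best


def _best_suffix_site(template: str, primer: str, min_len: int = 8, not_before: int = 0) -> tuple[int, int]:
    """(template position of the match start, length) for the primer suffix,
    extending each seed occurrence leftwards into the primer."""
    best: tuple[int, int] | None = None
    seed = primer[-min_len:]
    for pos in _seed_sites(template, seed):
        n = min_len
        while (
            n < len(primer)
            and pos - (n - min_len) - 1 >= 0
            and template[pos - (n - min_len) - 1] == primer[-(n + 1)]
        ):
            n += 1
        start = pos - (n - min_len)
        if start < not_before:
            continue
        if best is None or n > best[1]:
            best = (start, n)
    if best is None:
        raise LoopcraftError("primer 3' arm does not anneal to the template")
    return best


def simulate_quikchange(template: str, pair: PrimerPair) -> str:
    """Product of whole-plasmid mutagenesis: the template with the forward
    primer's span replaced by the primer sequence.

    Anneal sites come from maximal prefix/suffix matches on the template —
    the simulator never reads flank lengths recorded during design.
    """
    p = pair.forward.sequence
    i, n_pre = _best_prefix_site(template, p)
    j, n_suf = _best_suffix_site(template, p, not_before=i + 1)
    if j + n_suf <= i:
        raise LoopcraftError("primer arms anneal out of order")
    return template[:i] + p + template[j + n_suf :]


def simulate_pcr(template: str, forward: Primer, reverse: Primer) -> str:
    """Product of one PCR on the coding strand: the forward primer verbatim,
    the template core, then the reverse primer's reverse complement."""
    f = forward.sequence
    fi, fn = _best_suffix_site(template, f)  # the 3' arm must anneal
    r = _revcomp(reverse.sequence)
    ri, rn = _best_prefix_site(template, r)
    core_start = fi + fn
    if ri < core_start:
        raise LoopcraftError("reverse primer anneals upstream of the forward primer")
    return f + template[core_start:ri] + r


def assemble_gibson(amplicons: list[str], min_overlap: int = 15) -> str:
    """Join amplicons on exact terminal overlaps (isothermal assembly)."""
    if not amplicons:
        raise LoopcraftError("nothing to assemble")
    product = amplicons[0]
    for nxt in amplicons[1:]:
        ov = 0
        for n in range(min(len(product), len(nxt)), min_overlap - 1, -1):
            if product.endswith(nxt[:n]):
                ov = n
                break
        if ov == 0:
            raise LoopcraftError(
                f"no exact terminal overlap of >= {min_overlap} nt between amplicons"
            )
        product = product + nxt[ov:]
    return product


def simulate_gibson_mutagenesis(template: str, design: GibsonDesign) -> str:
    """Run both PCRs on the wild-type template and assemble the amplicons."""
    p1, p2 = design.pairs
    a1 = simulate_pcr(template, p1.forward, p1.reverse)
    a2 = simulate_pcr(template, p2.forward, p2.reverse)
    return assemble_gibson([a1, a2])
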