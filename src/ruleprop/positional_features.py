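"""Site-specific annotation by template alignment and pattern matching.

Positional features (active sites, binding residues, modified residues)
cannot be placed by family membership alone: the rule nominates a template
sequence and a list of residue patterns located on that template.  A target
that meets the rule's common conditions is globally aligned to the template;
each pattern is then tested in the target at the alignment-mapped positions,
and a match yields a sequence-feature annotation at the *target* range.

Alignment defaults are field-standard: global (end gaps penalised) with
BLOSUM62, gap open 10, gap extend 0.5.  The first optimal alignment reported
by the aligner is used, which is deterministic for fixed inputs.
"""

from __future__ import annotations

import functools
import logging
import re
from dataclasses import dataclass, replace

from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import ProteinRecord
from .rule_model import Evidence, PositionalPattern, Rule

logger = logging.getLogger(__name__)

#: The standard amino-acid alphabet plus the ambiguity symbol.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class PositionMap:
    """Template position -> target position (both 1-based inclusive).

    Template positions aligned to a gap in the target are absent.  The map
    is strictly increasing: for mapped t1 < t2, map(t1) < map(t2).
    """

    pairs: dict[int, int]

    def __post_init__(self):
        prev = 0
        for t in sorted(self.pairs):
            q = self.pairs[t]
            if q <= prev:
                raise ValueError(f"position map not strictly increasing at template {t}")
            prev = q

    def get(self, template_pos: int) -> int | None:
        return self.pairs.get(template_pos)


@functools.lru_cache(maxsize=8)
def _aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_alphabet(seq: str, name: str) -> None:
    for ch in seq:
        if ch not in _ALLOWED:
            raise ValueError(f"non-amino-acid symbol '{ch}' in {name} sequence")


def align_to_template(
    target: str,
    template: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PositionMap:
    """Globally align ``target`` to ``template`` and return the position map.

    Both sequences must be non-empty and drawn from the 20 standard amino
    acids plus ``X``; any other symbol is an error naming the offender.
    """
    if not target or not template:
        raise ValueError("cannot align empty sequences")
    _check_alphabet(target, "target")
    _check_alphabet(template, "template")
    alignment = _aligner(gap_open, gap_extend).align(template, target)[0]
    template_blocks, target_blocks = alignment.aligned
    pairs: dict[int, int] = {}
    for (ts, te), (qs, _qe) in zip(template_blocks, target_blocks):
        for k in range(int(te) - int(ts)):
            pairs[int(ts) + k + 1] = int(qs) + k + 1
    return PositionMap(pairs)


@functools.lru_cache(maxsize=512)
def compile_pattern(pattern: str) -> re.Pattern:
    """Compile a PROSITE-style pattern into a regular expression.

    Supported grammar: literal residues, ``x`` wildcard, ``[ABC]``
    alternatives, ``{ABC}`` exclusions, ``(n)`` / ``(n,m)`` repeats; elements
    may be separated by ``-`` and terminated by ``.``.  Anchors are not
    supported (patterns are located by the template range, not by the
    sequence ends).
    """
    body = pattern.strip().rstrip(".")
    if not body:
        raise ValueError("empty pattern")
    parts: list[str] = []
    i = 0
    while i < len(body):
        ch = body[i]
        if ch == "-":
            i += 1
            continue
        if ch == "x":
            elem = "."
        elif ch == "[":
            j = body.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed '[' in pattern '{pattern}'")
            elem = "[" + body[i + 1 : j] + "]"
            i = j
        elif ch == "{":
            j = body.find("}", i)
            if j < 0:
                raise ValueError(f"unclosed '{{' in pattern '{pattern}'")
            elem = "[^" + body[i + 1 : j] + "]"
            i = j
        elif ch.isalpha():
            elem = ch.upper()
        else:
            raise ValueError(f"unexpected symbol '{ch}' in pattern '{pattern}'")
        i += 1
        if i < len(body) and body[i] == "(":
            j = body.find(")", i)
            if j < 0:
                raise ValueError(f"unclosed '(' in pattern '{pattern}'")
            rep = body[i + 1 : j]
            if "," in rep:
                lo, hi = rep.split(",")
                elem += f"{{{int(lo)},{int(hi)}}}"
            else:
                elem += f"{{{int(rep)}}}"
            i = j + 1
        parts.append(elem)
    return re.compile("".join(parts))


def match_pattern(
    target: str, pattern: PositionalPattern, position_map: PositionMap
) -> tuple[int, int] | None:
    """Test one pattern at the alignment-mapped target positions.

    Returns the 1-based inclusive target range iff every template position
    of the pattern is mapped, the mapped positions are contiguous (a site
    interrupted by a target insertion is not the annotated site), and the
    target substring over the range matches the pattern; ``None`` otherwise.
    """
    ts, te = pattern.template_start, pattern.template_end
    mapped = [position_map.get(t) for t in range(ts, te + 1)]
    if any(m is None for m in mapped):
        return None
    start, end = mapped[0], mapped[-1]
    if end - start != te - ts:  # insertion inside the site
        return None
    if compile_pattern(pattern.pattern).fullmatch(target[start - 1 : end]):
        return (start, end)
    return None


def propagate_features(rule: Rule, record: ProteinRecord):
    """Propagate a rule's positional features onto one record.

    The caller guarantees the record already satisfies the rule's common
    conditions.  A record without sequence cannot be aligned: a warning is
    logged and no features are produced.
    """
    from .engine import AnnotationResult  # lazy: engine imports this module

    block = rule.positional
    if block is None:
        return []
    if not record.sequence:
        logger.warning(
            "rule %s: record %s has no sequence; positional features skipped",
            rule.rule_id, record.accession,
        )
        return []
    position_map = align_to_template(record.sequence, block.template_sequence)
    evidence = Evidence(source_rule=rule.rule_id)
    results = []
    for pat in block.patterns:
        rng = match_pattern(record.sequence, pat, position_map)
        if rng is not None:
            results.append(
                AnnotationResult(
                    record.accession,
                    replace(pat.annotation, position=rng),
                    evidence,
                    provenance="positional",
                )
            )
    return results
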