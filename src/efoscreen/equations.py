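"""Reading and writing consensus equations in the compact text dialect.

Consensus models are printed as signed linear combinations whose variable
names concatenate score type, pose aggregation and monomer, e.g.::

    −1.00 CsoptmeanC + 1.30 CSbestA

Parsing is case-insensitive and tolerant of the typographic variants that
occur in published tables (Unicode minus vs ASCII hyphen, ``CSoptmean``
vs ``Csoptmean``, ``CSBest``).  The bare score token ``C`` is normalized
to CS with a recorded warning, matching a known table typo.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .channels import ChannelKey

_MINUS = "−"  # the Unicode minus used on output


class EquationParseError(ValueError):
    """Unparseable equation text; message carries the token position."""


class EquationNormalizationWarning(UserWarning):
    """A token required non-trivial normalization (e.g. 'C' -> CS)."""


@dataclass(frozen=True)
class EquationTerm:
    """One term of a parsed equation: channel identity without frame or
    variant binding (the table dialect does not carry them)."""

    coefficient: float
    score_type: str
    aggregation: str
    monomer: str

    def bind(self, frame_ns: int, variant: str = "RAW") -> "ConsensusTermLike":
        from .efo import ConsensusTerm
        return ConsensusTerm(
            coefficient=self.coefficient,
            channel=ChannelKey(frame_ns=frame_ns, monomer=self.monomer,
                               score_type=self.score_type,
                               aggregation=self.aggregation,
                               variant=variant))


@dataclass(frozen=True)
class ParsedEquation:
    terms: tuple
    warnings: tuple

    def __len__(self) -> int:
        return len(self.terms)


_NAME_RE = re.compile(r"^(csopt|cs|ps|c)(best|mean)([a-d])$")
_NUM_RE = re.compile(r"^[+\-−]?\d+(\.\d+)?$")
_SCORE_CANON = {"ps": "PS", "cs": "CS", "csopt": "CSOPT", "c": "CS"}
_SCORE_PRINT = {"PS": "PS", "CS": "CS", "CSOPT": "Csopt"}


def _coef_repr(c: float) -> str:
    """Two-decimal coefficients; three decimals below 0.10 so that small
    printed values (0.082, 0.060) survive a round trip."""
    mag = abs(c)
    text = f"{mag:.3f}" if mag < 0.0995 else f"{mag:.2f}"
    return text


def format_equation(terms) -> str:
    """Render terms (ConsensusModel, ParsedEquation or term iterable) in
    the canonical dialect, Unicode minus on output."""
    seq = getattr(terms, "terms", terms)
    parts: list[str] = []
    for i, term in enumerate(seq):
        coef = term.coefficient
        if hasattr(term, "channel"):
            st, agg, mono = (term.channel.score_type,
                             term.channel.aggregation, term.channel.monomer)
        else:
            st, agg, mono = term.score_type, term.aggregation, term.monomer
        name = f"{_SCORE_PRINT[st]}{agg.lower()}{mono}"
        body = f"{_coef_repr(coef)} {name}"
        if i == 0:
            parts.append(f"{_MINUS}{body}" if coef < 0 else body)
        else:
            parts.append(f"{'+' if coef >= 0 else _MINUS} {body}")
    return " ".join(parts)


def parse_equation(text: str) -> ParsedEquation:
    """Parse the dialect into terms; raises EquationParseError with the
    offending token position on failure."""
    tokens = text.split()
    if not tokens:
        raise EquationParseError("empty equation")
    terms: list[EquationTerm] = []
    notes: list[str] = []
    sign = 1.0
    coef: float | None = None
    have_sign = False
    for pos, raw in enumerate(tokens):
        tok = raw.replace(_MINUS, "-")
        if tok in ("+", "-"):
            if have_sign or coef is not None:
                raise EquationParseError(
                    f"unexpected sign token {raw!r} at position {pos}")
            sign = 1.0 if tok == "+" else -1.0
            have_sign = True
            continue
        if _NUM_RE.match(tok):
            if coef is not None:
                raise EquationParseError(
                    f"unexpected number {raw!r} at position {pos}")
            value = float(tok)
            if tok[0] in "+-":
                if have_sign:
                    raise EquationParseError(
                        f"doubled sign at position {pos}: {raw!r}")
                coef = value
            else:
                coef = sign * value
            continue
        m = _NAME_RE.match(tok.lower())
        if m is None:
            raise EquationParseError(
                f"unparseable token {raw!r} at position {pos}")
        score_tok, agg_tok, mono_tok = m.groups()
        if score_tok == "c":
            note = (f"score token {raw!r} at position {pos} "
                    "normalized from 'C' to CS")
            notes.append(note)
            warnings.warn(note, EquationNormalizationWarning, stacklevel=2)
        terms.append(EquationTerm(
            coefficient=coef if coef is not None else sign * 1.0,
            score_type=_SCORE_CANON[score_tok],
            aggregation=agg_tok.upper(),
            monomer=mono_tok.upper()))
        sign, coef, have_sign = 1.0, None, False
    if coef is not None or have_sign:
        raise EquationParseError("equation ends with a dangling sign/number")
    if not terms:
        raise EquationParseError("equation contains no terms")
    return ParsedEquation(terms=tuple(terms), warnings=tuple(notes))
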