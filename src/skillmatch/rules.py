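"""Boolean movement rules: definition, text format, English rendering, matching.

A *condition* constrains the motion of one joint: starting from an anchor
frame, the joint's displacement along an axis (or the change in the angle at
the joint) must satisfy a comparator against a threshold within a strict time
window ("changes at least 5 cm in under 1 second").  Conditions combine into
an expression tree with AND, OR and IF-THEN nodes; a named tree is a *rule*.

Matching slides an anchor across the stream.  From each admissible anchor the
window grows frame by frame up to the rule's longest condition window; a
condition is marked satisfied at the first frame whose displacement from the
anchor meets it.  The rule matches at the first frame where the Boolean
expression over marked conditions is true (and at least one condition is
actually satisfied — an IF-THEN made vacuously true by an unmet antecedent
never fires on its own).  The reported match starts at the earliest
supra-threshold evidence frame and ends at the frame that completed the
expression; scanning then resumes one full window after the match end, so a
single continuous movement is counted once.  Anchors inside exclusion
intervals are skipped and no window crosses an exclusion boundary.

Comparator semantics follow the published jump/sidestep rule set: "changes at
least N" compares |displacement| >= N (a jump is a jump whichever way the
baseline drifted), while the explicit "changes less than -N" clause is signed.
X is the player's right, Y is up, so "Vertical" = Y and "Horizontal" = X.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import RuleSyntaxError, ValidationError
from .skeleton import (
    FIRST_CHILD,
    JOINT_BY_NAME,
    PARENT,
    JointId,
    SkeletonStream,
    TrackingState,
)

AXIS_NAMES = {"X": 0, "Y": 1, "Z": 2}
AXIS_LETTERS = {v: k for k, v in AXIS_NAMES.items()}

COMPARATORS = ("abs_ge", "ge", "le")
_CMP_TOKENS = {"ABS>=": "abs_ge", ">=": "ge", "<=": "le"}
_CMP_BY_NAME = {v: k for k, v in _CMP_TOKENS.items()}


@dataclass(frozen=True)
class Condition:
    """A single kinematic constraint on one joint.

    kind : "disp" (axis displacement, metres) or "angle" (joint angle change,
        degrees); "angle" conditions carry no axis.
    comparator : "abs_ge" (|d| >= threshold), "ge" (d >= threshold) or
        "le" (d <= threshold), where d is measured relative to the anchor.
    window_s : strict upper bound on elapsed time from the anchor.
    label : optional plain-English display text; excluded from equality.
    """

    kind: str
    joint: JointId
    axis: int | None
    comparator: str
    threshold: float
    window_s: float
    label: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.kind not in ("disp", "angle"):
            raise ValidationError(f"unknown condition kind {self.kind!r}")
        if self.kind == "disp" and self.axis not in (0, 1, 2):
            raise ValidationError("displacement conditions need an axis X, Y or Z")
        if self.kind == "angle" and self.axis is not None:
            raise ValidationError("joint-angle conditions carry no axis")
        if self.comparator not in COMPARATORS:
            raise ValidationError(f"unknown comparator {self.comparator!r}")
        if not (self.window_s > 0 and math.isfinite(self.window_s)):
            raise ValidationError("window_s must be positive and finite")
        if not math.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")

    def test(self, d: float) -> bool:
        if self.comparator == "abs_ge":
            return abs(d) >= self.threshold
        if self.comparator == "ge":
            return d >= self.threshold
        return d <= self.threshold


@dataclass(frozen=True)
class And:
    children: tuple

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValidationError("AND needs at least 2 children")


@dataclass(frozen=True)
class Or:
    children: tuple

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValidationError("OR needs at least 2 children")


@dataclass(frozen=True)
class Then:
    """IF-THEN: true when the antecedent is unsatisfied (vacuous) or the
    consequent is satisfied at/after the antecedent's satisfying frame."""

    antecedent: object
    consequent: object


RuleExpr = Condition | And | Or | Then


@dataclass(frozen=True)
class Rule:
    name: str
    expr: RuleExpr

    def __post_init__(self):
        if not self.name:
            raise ValidationError("rule name must be nonempty")

    def leaves(self) -> list[Condition]:
        out: list[Condition] = []

        def walk(node):
            if isinstance(node, Condition):
                out.append(node)
            elif isinstance(node, (And, Or)):
                for c in node.children:
                    walk(c)
            elif isinstance(node, Then):
                walk(node.antecedent)
                walk(node.consequent)
            else:  # pragma: no cover
                raise ValidationError(f"unknown node {node!r}")

        walk(self.expr)
        return out

    @property
    def max_window_s(self) -> float:
        return max(c.window_s for c in self.leaves())


@dataclass
class MatchResult:
    """One detected movement: [start_s, end_s] with frame indices."""

    rule_name: str
    start_s: float
    end_s: float
    start_frame: int
    end_frame: int


@dataclass
class MatchSummary:
    """Per-rule counts and time points; the tool's primary output."""

    matches: dict[str, list[MatchResult]]
    metadata: dict

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(ms) for name, ms in self.matches.items()}

    def to_json(self, destination=None) -> str:
        payload = json.dumps(
            {
                "metadata": self.metadata,
                "rules": {
                    name: {
                        "count": len(ms),
                        "matches": [
                            {"start_s": round(m.start_s, 6), "end_s": round(m.end_s, 6)}
                            for m in ms
                        ],
                    }
                    for name, ms in self.matches.items()
                },
            },
            sort_keys=True,
            indent=2,
        )
        if destination is not None:
            Path(destination).write_text(payload + "\n")
        return payload

    def to_csv(self, destination) -> None:
        lines = ["rule,start_s,end_s"]
        for name, ms in self.matches.items():
            for m in ms:
                lines.append(f"{name},{m.start_s:.6f},{m.end_s:.6f}")
        Path(destination).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_json(cls, source) -> "MatchSummary":
        data = json.loads(Path(source).read_text() if Path(str(source)).exists() else source)
        matches = {
            name: [
                MatchResult(name, m["start_s"], m["end_s"], -1, -1)
                for m in spec["matches"]
            ]
            for name, spec in data["rules"].items()
        }
        return cls(matches=matches, metadata=data.get("metadata", {}))


# -- textual rule format (.krt) --------------------------------------------

_TOKEN_RE = re.compile(
    r"(?P<ws>\s+)|(?P<cmp>ABS>=|>=|<=)|(?P<paren>[()])|"
    r"(?P<num>[-+]?(?:\d+\.?\d*|\.\d+))|(?P<word>[A-Za-z_][A-Za-z0-9_]*)"
)


@dataclass
class _Token:
    text: str
    line: int
    col: int


def _tokenize(lines: list[str], start_line: int) -> tuple[list[_Token], dict[int, str]]:
    """Tokenize rule body lines; `#:` comments become labels for the next leaf."""
    tokens: list[_Token] = []
    labels: dict[int, str] = {}  # index into tokens where the label applies
    pending: str | None = None
    for ln, raw in enumerate(lines, start=start_line):
        line = raw
        if line.lstrip().startswith("#:"):
            pending = line.lstrip()[2:].strip()
            continue
        if "#" in line:
            line = line[: line.index("#")]
        pos = 0
        while pos < len(line):
            m = _TOKEN_RE.match(line, pos)
            if m is None:
                raise RuleSyntaxError(f"unexpected character {line[pos]!r}", ln, pos + 1)
            if m.lastgroup != "ws":
                if pending is not None:
                    labels[len(tokens)] = pending
                    pending = None
                tokens.append(_Token(m.group(), ln, m.start() + 1))
            pos = m.end()
    return tokens, labels


class _Parser:
    def __init__(self, tokens: list[_Token], labels: dict[int, str]):
        self.tokens = tokens
        self.labels = labels
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i].text if self.i < len(self.tokens) else None

    def next(self, expected: str | None = None) -> _Token:
        if self.i >= len(self.tokens):
            last = self.tokens[-1] if self.tokens else _Token("", 1, 1)
            raise RuleSyntaxError(
                f"unexpected end of rule{f', expected {expected!r}' if expected else ''}",
                last.line,
                last.col,
            )
        tok = self.tokens[self.i]
        self.i += 1
        if expected is not None and tok.text != expected:
            raise RuleSyntaxError(f"expected {expected!r}, got {tok.text!r}", tok.line, tok.col)
        return tok

    # precedence: THEN < OR < AND (AND binds tightest); parentheses override.
    def parse_expr(self) -> RuleExpr:
        left = self.parse_or()
        while self.peek() == "THEN":
            self.next()
            right = self.parse_or()
            left = Then(left, right)
        return left

    def parse_or(self) -> RuleExpr:
        parts = [self.parse_and()]
        while self.peek() == "OR":
            self.next()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> RuleExpr:
        parts = [self.parse_atom()]
        while self.peek() == "AND":
            self.next()
            parts.append(self.parse_atom())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_atom(self) -> RuleExpr:
        tok_index = self.i
        tok = self.next("a condition or '('" if self.peek() is None else None)
        if tok.text == "(":
            expr = self.parse_expr()
            self.next(")")
            return expr
        if tok.text in ("DISP", "ANGLE"):
            return self._parse_leaf(tok, self.labels.get(tok_index))
        raise RuleSyntaxError(f"expected DISP, ANGLE or '(', got {tok.text!r}", tok.line, tok.col)

    def _parse_leaf(self, head: _Token, label: str | None) -> Condition:
        joint_tok = self.next()
        joint = JOINT_BY_NAME.get(joint_tok.text.lower())
        if joint is None:
            raise RuleSyntaxError(f"unknown joint name {joint_tok.text!r}",
                                  joint_tok.line, joint_tok.col)
        axis = None
        if head.text == "DISP":
            axis_tok = self.next()
            if axis_tok.text.upper() not in AXIS_NAMES:
                raise RuleSyntaxError(f"expected axis X, Y or Z, got {axis_tok.text!r}",
                                      axis_tok.line, axis_tok.col)
            axis = AXIS_NAMES[axis_tok.text.upper()]
        cmp_tok = self.next()
        if cmp_tok.text not in _CMP_TOKENS:
            raise RuleSyntaxError(f"expected ABS>=, >= or <=, got {cmp_tok.text!r}",
                                  cmp_tok.line, cmp_tok.col)
        thr_tok = self.next()
        try:
            threshold = float(thr_tok.text)
        except ValueError:
            raise RuleSyntaxError(f"expected a number, got {thr_tok.text!r}",
                                  thr_tok.line, thr_tok.col) from None
        self.next("WITHIN")
        win_tok = self.next()
        try:
            window = float(win_tok.text)
        except ValueError:
            raise RuleSyntaxError(f"expected a number, got {win_tok.text!r}",
                                  win_tok.line, win_tok.col) from None
        if window <= 0:
            raise RuleSyntaxError("window must be positive", win_tok.line, win_tok.col)
        try:
            return Condition(
                kind="disp" if head.text == "DISP" else "angle",
                joint=joint,
                axis=axis,
                comparator=_CMP_TOKENS[cmp_tok.text],
                threshold=threshold,
                window_s=window,
                label=label,
            )
        except ValidationError as exc:
            raise RuleSyntaxError(str(exc), head.line, head.col) from None


def parse_rule(text: str) -> Rule:
    """Parse the line-oriented ``.krt`` rule format.

    ``RULE <name>`` header, then an expression over ``DISP``/``ANGLE``
    condition leaves and ``AND``/``OR``/``THEN`` operators with parentheses
    for grouping.  ``#`` starts a comment; ``#: <text>`` attaches a display
    label to the next condition.
    """
    lines = text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        header_idx = i
        break
    if header_idx is None or not lines[header_idx].strip().startswith("RULE"):
        raise RuleSyntaxError("rule file must start with 'RULE <name>'", 1, 1)
    name = lines[header_idx].strip()[4:].strip()
    if not name:
        raise RuleSyntaxError("rule name must be nonempty", header_idx + 1, 1)
    tokens, labels = _tokenize(lines[header_idx + 1:], header_idx + 2)
    if not tokens:
        raise RuleSyntaxError("rule has no conditions", header_idx + 1, 1)
    parser = _Parser(tokens, labels)
    expr = parser.parse_expr()
    if parser.peek() is not None:
        tok = parser.tokens[parser.i]
        raise RuleSyntaxError(f"unexpected trailing token {tok.text!r}", tok.line, tok.col)
    return Rule(name=name, expr=expr)


def _precedence(node: RuleExpr) -> int:
    if isinstance(node, Then):
        return 1
    if isinstance(node, Or):
        return 2
    if isinstance(node, And):
        return 3
    return 4


def serialize_rule(rule: Rule) -> str:
    """Render a rule back to the ``.krt`` text format (parse round-trips)."""

    def leaf(c: Condition) -> list[str]:
        out = []
        if c.label:
            out.append(f"#: {c.label}")
        num = lambda x: repr(float(x))  # shortest exact decimal round-trips
        if c.kind == "disp":
            out.append(
                f"DISP {c.joint.name.lower()} {AXIS_LETTERS[c.axis]} "
                f"{_CMP_BY_NAME[c.comparator]} {num(c.threshold)} WITHIN {num(c.window_s)}"
            )
        else:
            out.append(
                f"ANGLE {c.joint.name.lower()} {_CMP_BY_NAME[c.comparator]} "
                f"{num(c.threshold)} WITHIN {num(c.window_s)}"
            )
        return out

    def walk(node: RuleExpr, parent_prec: int) -> list[str]:
        if isinstance(node, Condition):
            return leaf(node)
        prec = _precedence(node)
        if isinstance(node, Then):
            parts = [walk(node.antecedent, prec + 1), ["THEN"], walk(node.consequent, prec + 1)]
        else:
            op = "AND" if isinstance(node, And) else "OR"
            parts = []
            for i, child in enumerate(node.children):
                if i:
                    parts.append([op])
                # prec+1 so a same-operator child keeps explicit parentheses
                # instead of being flattened into the parent on reparse
                parts.append(walk(child, prec + 1))
        lines = [ln for part in parts for ln in part]
        if prec < parent_prec:
            lines = ["("] + lines + [")"]
        return lines

    return "\n".join([f"RULE {rule.name}"] + walk(rule.expr, 0)) + "\n"


def read_rule(source) -> Rule:
    return parse_rule(Path(source).read_text())


def write_rule(rule: Rule, destination) -> None:
    Path(destination).write_text(serialize_rule(rule))


# -- plain-English rendering ------------------------------------------------

_DIRECTION_WORD = {0: "Horizontal", 1: "Vertical", 2: "Depth"}


def _joint_display(joint: JointId) -> str:
    name = joint.name.lower()
    for side in ("left", "right"):
        if name.endswith("_" + side):
            return f"{side} {name[: -len(side) - 1].replace('_', ' ')}"
    return name.replace("_", " ")


def _fmt_num(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return f"{x:g}"


def _fmt_window(w: float) -> str:
    s = _fmt_num(w)
    if s.startswith("0."):
        s = s[1:]
    unit = "second" if w == 1 else "seconds"
    return f"{s} {unit}"


def condition_english(cond: Condition) -> str:
    """Canonical clause text (the display label, when present, wins)."""
    if cond.label:
        return cond.label
    if cond.kind == "disp":
        subject = f"{_DIRECTION_WORD[cond.axis]} movement of the {_joint_display(cond.joint)}"
        if cond.comparator == "le":
            verb = f"changes less than {_fmt_num(cond.threshold * 100)} centimetres"
        else:
            verb = f"changes at least {_fmt_num(cond.threshold * 100)}cm"
    else:
        subject = f"The angle at the {_joint_display(cond.joint)}"
        if cond.comparator == "le":
            verb = f"changes less than {_fmt_num(cond.threshold)} degrees"
        else:
            verb = f"changes at least {_fmt_num(cond.threshold)} degrees"
    return f"{subject} {verb} in under {_fmt_window(cond.window_s)}"


def render_english(rule: Rule) -> str:
    """One clause per condition, operator words on their own lines."""

    def walk(node: RuleExpr) -> list[str]:
        if isinstance(node, Condition):
            return [condition_english(node)]
        if isinstance(node, Then):
            return walk(node.antecedent) + ["IF-THEN"] + walk(node.consequent)
        op = "AND" if isinstance(node, And) else "OR"
        lines: list[str] = []
        for i, child in enumerate(node.children):
            if i:
                lines.append(op)
            lines.extend(walk(child))
        return lines

    return "\n".join(walk(rule.expr))


# -- built-in rules ---------------------------------------------------------

def _disp(joint: JointId, axis: str, comparator: str, threshold: float,
          window: float, label: str) -> Condition:
    return Condition(kind="disp", joint=joint, axis=AXIS_NAMES[axis],
                     comparator=comparator, threshold=threshold,
                     window_s=window, label=label)


def builtin_jump() -> Rule:
    """The published jump rule: all four landmarks rise or fall >= 5 cm in
    under 1 s (head, both ankles, hip centre)."""
    return Rule(
        name="JUMP",
        expr=And(
            (
                _disp(JointId.HEAD, "Y", "abs_ge", 0.05, 1.0,
                      "Vertical movement of the head changes at least 5cm in under 1 second"),
                _disp(JointId.ANKLE_LEFT, "Y", "abs_ge", 0.05, 1.0,
                      "Vertical movement of the left ankle changes at least 5 cm in under 1 second"),
                _disp(JointId.ANKLE_RIGHT, "Y", "abs_ge", 0.05, 1.0,
                      "Vertical movement of the right ankle changes at least 5 cm in under 1 second"),
                _disp(JointId.HIP_CENTRE, "Y", "abs_ge", 0.05, 1.0,
                      "Vertical movement of the hip centre changes at least 5cm in under 1 second"),
            )
        ),
    )


_HIP_LABEL = "Horizontal Movement of the hip centre changes at least 10 cm in under .5 seconds"
_SHOULDER_LABEL = (
    "Horizontal movement of the shoulder centre changes at least 10 centimetres in under .5 seconds"
)


def builtin_sidestep() -> Rule:
    """The published sidestep rule: two mirrored trunk-plus-lead-foot
    branches joined by OR; the left-lead branch additionally requires the
    right foot to trail by at least 25 cm (preserved verbatim from the
    published rule set, including its left/right asymmetry)."""
    right_branch = And(
        (
            _disp(JointId.HIP_CENTRE, "X", "abs_ge", 0.10, 0.5, _HIP_LABEL),
            _disp(
                JointId.FOOT_RIGHT, "X", "abs_ge", 0.30, 0.3,
                "Horizontal movement of the right foot changes at least 30 centimetres in under .3 seconds",
            ),
            _disp(JointId.SHOULDER_CENTRE, "X", "abs_ge", 0.10, 0.5, _SHOULDER_LABEL),
        )
    )
    left_branch = And(
        (
            _disp(JointId.HIP_CENTRE, "X", "abs_ge", 0.10, 0.5, _HIP_LABEL),
            _disp(
                JointId.FOOT_LEFT, "X", "abs_ge", 0.30, 0.3,
                "Horizontal movement of the left foot changes at least 30 centimetres in under .3 seconds",
            ),
            _disp(JointId.SHOULDER_CENTRE, "X", "abs_ge", 0.10, 0.5, _SHOULDER_LABEL),
            _disp(
                JointId.FOOT_RIGHT, "X", "le", -0.25, 0.5,
                "Horizontal movement of the right foot changes less than -25 centimetres in under .5 seconds",
            ),
        )
    )
    return Rule(name="SIDESTEP", expr=Or((right_branch, left_branch)))


def builtin_rules() -> list[Rule]:
    return [builtin_jump(), builtin_sidestep()]


def load_builtin(name: str) -> Rule:
    """Parse a shipped ``.krt`` rule file ('jump' or 'sidestep')."""
    text = resources.files("skillmatch").joinpath(f"rules_data/{name}.krt").read_text()
    return parse_rule(text)


# -- joint-angle series ------------------------------------------------------

def joint_angle_series(stream: SkeletonStream, joint: JointId) -> np.ndarray:
    """Angle (degrees) at *joint* between the segments to its parent and to
    its first child in the kinematic tree; NaN where undefined or where any
    of the three joints is Not Tracked."""
    parent = PARENT[joint]
    child = FIRST_CHILD[joint]
    n = stream.n_frames
    if parent is None or child is None:
        return np.full(n, np.nan)
    p = stream.positions[:, int(parent)].astype(np.float64)
    q = stream.positions[:, int(joint)].astype(np.float64)
    c = stream.positions[:, int(child)].astype(np.float64)
    u = p - q
    v = c - q
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    bad = (
        (stream.states[:, int(parent)] == TrackingState.NOT_TRACKED)
        | (stream.states[:, int(joint)] == TrackingState.NOT_TRACKED)
        | (stream.states[:, int(child)] == TrackingState.NOT_TRACKED)
        | (nu == 0)
        | (nv == 0)
    )
    ang[bad] = np.nan
    return ang


# -- evaluation & matching ---------------------------------------------------

class _StreamCache:
    """Per-stream scalar series and admissibility arrays for the matcher."""

    def __init__(self, stream: SkeletonStream):
        self.stream = stream
        self.t = stream.timestamps
        self.run = stream.run_ids
        self.excluded = stream.excluded_mask
        self.states = stream.states
        self._series: dict = {}

    def series(self, cond: Condition) -> np.ndarray:
        key = (cond.kind, int(cond.joint), cond.axis)
        if key not in self._series:
            if cond.kind == "disp":
                self._series[key] = self.stream.positions[:, int(cond.joint), cond.axis].astype(
                    np.float64
                )
            else:
                self._series[key] = joint_angle_series(self.stream, cond.joint)
        return self._series[key]


def _first_satisfying(cond: Condition, cache: _StreamCache, anchor: int,
                      start_from: int | None = None) -> int | None:
    """First frame index j with 0 < t[j]-t[anchor] < window, in the anchor's
    non-excluded run, whose displacement from the anchor satisfies *cond*.
    Returns None when no such frame exists (including an untracked anchor)."""
    t = cache.t
    run = cache.run
    n = len(t)
    if cache.states[anchor, int(cond.joint)] == TrackingState.NOT_TRACKED:
        return None
    series = cache.series(cond)
    p0 = series[anchor]
    if not np.isfinite(p0):
        return None
    r = run[anchor]
    j = anchor + 1 if start_from is None else max(anchor + 1, start_from)
    t0 = t[anchor]
    w = cond.window_s
    joint = int(cond.joint)
    while j < n and t[j] - t0 < w:
        if run[j] != r:
            return None
        if cache.states[j, joint] != TrackingState.NOT_TRACKED:
            d = series[j] - p0
            if np.isfinite(d) and cond.test(d):
                return j
        j += 1
    return None


def evaluate_condition(cond: Condition, stream: SkeletonStream, anchor_index: int
                       ) -> tuple[bool, int | None]:
    """Evaluate one condition anchored at *anchor_index*.

    Returns (satisfied, index of the first satisfying frame or None).  A
    joint that is Not Tracked at the anchor makes the condition unsatisfied
    rather than raising.  The anchor must be a valid, non-excluded frame.
    """
    if not 0 <= anchor_index < stream.n_frames:
        raise ValidationError(f"anchor index {anchor_index} out of range")
    if stream.excluded_mask[anchor_index]:
        raise ValidationError(f"anchor index {anchor_index} is inside an exclusion interval")
    idx = _first_satisfying(cond, _StreamCache(stream), anchor_index)
    return (idx is not None, idx)


def _contains_then(node: RuleExpr) -> bool:
    if isinstance(node, Then):
        return True
    if isinstance(node, (And, Or)):
        return any(_contains_then(c) for c in node.children)
    return False


def _sat_index_from(node: RuleExpr, cache: _StreamCache, anchor: int, lo: int,
                    limit: int, leaf_memo: dict) -> int | None:
    """First frame index <= limit at which *node* is satisfied, using only
    evidence frames >= lo; None if unsatisfied by *limit*.  A Then whose
    antecedent is unsatisfied is vacuously satisfied at *lo*."""
    if isinstance(node, Condition):
        key = (id(node), lo)
        if key not in leaf_memo:
            leaf_memo[key] = _first_satisfying(node, cache, anchor, start_from=lo)
        idx = leaf_memo[key]
        return idx if idx is not None and idx <= limit else None
    if isinstance(node, And):
        worst = lo
        for child in node.children:
            idx = _sat_index_from(child, cache, anchor, lo, limit, leaf_memo)
            if idx is None:
                return None
            worst = max(worst, idx)
        return worst
    if isinstance(node, Or):
        best = None
        for child in node.children:
            idx = _sat_index_from(child, cache, anchor, lo, limit, leaf_memo)
            if idx is not None and (best is None or idx < best):
                best = idx
        return best
    if isinstance(node, Then):
        a = _sat_index_from(node.antecedent, cache, anchor, lo, limit, leaf_memo)
        if a is None:
            return lo  # vacuously true; fires no match on its own
        return _sat_index_from(node.consequent, cache, anchor, a, limit, leaf_memo)
    raise ValidationError(f"unknown node {node!r}")  # pragma: no cover


def _try_anchor(rule: Rule, cache: _StreamCache, anchor: int,
                leaves: list[Condition], has_then: bool) -> tuple[int, int] | None:
    """Attempt a match anchored at *anchor*; returns (start_idx, end_idx)."""
    t = cache.t
    n = len(t)
    w_max = rule.max_window_s
    # last admissible window frame
    leaf_memo: dict = {}

    def leaf_first(c: Condition) -> int | None:
        key = (id(c), anchor)
        if key not in leaf_memo:
            leaf_memo[key] = _first_satisfying(c, cache, anchor)
        return leaf_memo[key]

    def evidence_start(end: int) -> int:
        firsts = [leaf_first(c) for c in leaves]
        firsts = [f for f in firsts if f is not None and f <= end]
        return min(firsts) if firsts else end

    if not has_then:
        # AND/OR truth is monotone in the end frame, so the first frame that
        # completes the expression is its satisfaction index at full window.
        end = _sat_index_from(rule.expr, cache, anchor, anchor, n, leaf_memo)
        if end is None:
            return None
        return (evidence_start(end), end)

    j = anchor + 1
    r = cache.run[anchor]
    while j < n and t[j] - t[anchor] < w_max:
        if cache.run[j] != r:
            return None
        sat = _sat_index_from(rule.expr, cache, anchor, anchor, j, leaf_memo)
        if sat is not None and any(
            (f := leaf_first(c)) is not None and f <= j for c in leaves
        ):
            return (evidence_start(j), j)
        j += 1
    return None


def match_rule(rule: Rule, stream: SkeletonStream) -> list[MatchResult]:
    """Detect and count movements matching *rule* in *stream*.

    Anchors are scanned left to right (excluded frames skipped); a failed
    anchor advances by one frame; after a valid match, scanning resumes one
    maximal condition window after the match's end frame so a single
    continuous movement is not counted twice.  Matched intervals never
    overlap.
    """
    cache = _StreamCache(stream)
    leaves = rule.leaves()
    has_then = _contains_then(rule.expr)
    t = cache.t
    n = stream.n_frames
    matches: list[MatchResult] = []
    i = 0
    while i < n - 1:
        if cache.excluded[i]:
            i += 1
            continue
        res = _try_anchor(rule, cache, i, leaves, has_then)
        if res is None:
            i += 1
            continue
        start_idx, end_idx = res
        matches.append(
            MatchResult(rule.name, float(t[start_idx]), float(t[end_idx]), start_idx, end_idx)
        )
        resume_t = t[end_idx] + rule.max_window_s
        i = max(int(np.searchsorted(t, resume_t, side="left")), end_idx + 1)
    return matches


def match_all(rules: list[Rule], stream: SkeletonStream) -> MatchSummary:
    """Evaluate each rule independently over the whole stream."""
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ValidationError("rule names must be unique")
    return MatchSummary(
        matches={r.name: match_rule(r, stream) for r in rules},
        metadata=dict(stream.metadata),
    )
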