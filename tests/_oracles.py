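"""Independent reference implementations used only by the tests.

The matcher oracle re-derives every match by exhaustively testing each
(anchor, end-frame) pair with naive per-pair scans, sharing no code with the
package's matcher.  The stream/rule generators produce randomised inputs for
the equivalence property.
"""

from __future__ import annotations

import numpy as np

from skillmatch.rules import And, Condition, Or, Rule, Then, joint_angle_series
from skillmatch.skeleton import N_JOINTS, JointId, SkeletonStream, TrackingState


def _series(stream: SkeletonStream, cond: Condition) -> np.ndarray:
    if cond.kind == "disp":
        return stream.positions[:, int(cond.joint), cond.axis].astype(float)
    return joint_angle_series(stream, cond.joint)


def _cmp(cond: Condition, d: float) -> bool:
    if cond.comparator == "abs_ge":
        return abs(d) >= cond.threshold
    if cond.comparator == "ge":
        return d >= cond.threshold
    return d <= cond.threshold


def _leaf_first(stream, cond, anchor, end, lo):
    """First index in [max(anchor+1, lo), end] whose displacement from the
    anchor satisfies cond, respecting its window, the anchor's run, and
    tracking states; None otherwise."""
    t = stream.timestamps
    run = stream.run_ids
    if stream.states[anchor, int(cond.joint)] == TrackingState.NOT_TRACKED:
        return None
    series = _series(stream, cond)
    p0 = series[anchor]
    if not np.isfinite(p0):
        return None
    for k in range(max(anchor + 1, lo), end + 1):
        if run[k] != run[anchor]:
            return None
        if t[k] - t[anchor] >= cond.window_s:
            return None
        if stream.states[k, int(cond.joint)] == TrackingState.NOT_TRACKED:
            continue
        d = series[k] - p0
        if np.isfinite(d) and _cmp(cond, d):
            return k
    return None


def _node_sat(stream, node, anchor, end, lo):
    """Earliest index <= end at which the node is satisfied with evidence
    frames >= lo; a Then with unmet antecedent is vacuously satisfied at lo."""
    if isinstance(node, Condition):
        return _leaf_first(stream, node, anchor, end, lo)
    if isinstance(node, And):
        worst = lo
        for child in node.children:
            idx = _node_sat(stream, child, anchor, end, lo)
            if idx is None:
                return None
            worst = max(worst, idx)
        return worst
    if isinstance(node, Or):
        idxs = [_node_sat(stream, child, anchor, end, lo) for child in node.children]
        idxs = [i for i in idxs if i is not None]
        return min(idxs) if idxs else None
    if isinstance(node, Then):
        a = _node_sat(stream, node.antecedent, anchor, end, lo)
        if a is None:
            return lo
        return _node_sat(stream, node.consequent, anchor, end, a)
    raise AssertionError(node)


def oracle_match(rule: Rule, stream: SkeletonStream) -> list[tuple[int, int]]:
    """Brute-force matcher: (start_frame, end_frame) per match."""
    leaves = rule.leaves()
    w_max = rule.max_window_s
    t = stream.timestamps
    n = stream.n_frames
    excluded = stream.excluded_mask
    run = stream.run_ids
    out: list[tuple[int, int]] = []
    i = 0
    while i < n - 1:
        if excluded[i]:
            i += 1
            continue
        found = None
        j = i + 1
        while j < n and t[j] - t[i] < w_max and run[j] == run[i]:
            sat = _node_sat(stream, rule.expr, i, j, i)
            firsts = [
                f for c in leaves if (f := _leaf_first(stream, c, i, j, i)) is not None
            ]
            if sat is not None and firsts:
                found = (min(firsts), j)
                break
            j += 1
        if found is None:
            i += 1
            continue
        out.append(found)
        resume_t = t[found[1]] + w_max
        k = found[1] + 1
        while k < n and t[k] < resume_t:
            k += 1
        i = k
    return out


# -- randomised inputs -------------------------------------------------------

_JOINT_POOL = [JointId.HEAD, JointId.HIP_CENTRE, JointId.ANKLE_LEFT,
               JointId.FOOT_RIGHT, JointId.SHOULDER_CENTRE, JointId.ELBOW_LEFT]


def random_stream(rng: np.random.Generator, *, max_frames: int = 90) -> SkeletonStream:
    n = int(rng.integers(25, max_frames))
    rate = 30.0
    t = np.arange(n) / rate
    pos = np.cumsum(rng.normal(0.0, 0.02, size=(n, N_JOINTS, 3)), axis=0)
    pos += rng.normal(0.0, 0.5, size=(1, N_JOINTS, 3))
    states = np.full((n, N_JOINTS), int(TrackingState.TRACKED), dtype=np.uint8)
    drop = rng.random((n, N_JOINTS))
    states[drop < 0.02] = int(TrackingState.NOT_TRACKED)
    states[(drop >= 0.02) & (drop < 0.05)] = int(TrackingState.INFERRED)
    orients = np.zeros((n, N_JOINTS, 3), dtype=np.float32)
    exclusions = []
    if rng.random() < 0.35:
        a = float(rng.uniform(0, t[-1] * 0.8))
        exclusions.append((a, a + float(rng.uniform(0.1, 0.8))))
    return SkeletonStream(t, pos.astype(np.float32), states, orients,
                          nominal_rate=rate, exclusions=exclusions)


def random_condition(rng: np.random.Generator) -> Condition:
    comparator = rng.choice(["abs_ge", "abs_ge", "ge", "le"])
    threshold = float(rng.uniform(0.01, 0.15))
    if comparator == "le":
        threshold = -threshold
    return Condition(
        kind="disp",
        joint=_JOINT_POOL[int(rng.integers(len(_JOINT_POOL)))],
        axis=int(rng.integers(3)),
        comparator=str(comparator),
        threshold=threshold,
        window_s=float(rng.uniform(0.1, 0.6)),
    )


def random_rule(rng: np.random.Generator, name: str = "RANDOM") -> Rule:
    shape = rng.random()
    if shape < 0.25:
        expr = random_condition(rng)
    elif shape < 0.55:
        expr = And(tuple(random_condition(rng) for _ in range(int(rng.integers(2, 4)))))
    elif shape < 0.75:
        expr = Or(tuple(random_condition(rng) for _ in range(2)))
    elif shape < 0.9:
        expr = Or(
            (
                And((random_condition(rng), random_condition(rng))),
                random_condition(rng),
            )
        )
    else:
        expr = Then(random_condition(rng), random_condition(rng))
    return Rule(name=name, expr=expr)
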