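"""Score propagation and call logic.

Each branch network outputs child probabilities that sum to 1 *locally*.
Hierarchy-consistent scores are obtained by walking the tree from the root
(score 1.0) and multiplying each child's branch probability by its parent's
propagated score.  Consequences:

* major-category scores sum to 1, as do terminal scores;
* every internal node's score equals the sum of its children's scores;
* scores are non-increasing along any root-to-leaf path, so thresholding on
  score gives a *dynamic* prediction depth — the call is reported as deep as
  confidence supports.

Because major scores sum to 1, a call threshold above 0.5 guarantees at most
one major category can be called; thresholds <= 0.5 are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hierarchy import LabelHierarchy

_SUM_TOL = 1e-4  # tolerance for validating incoming branch vectors

NO_CALL = "<no_call>"


@dataclass
class ScoreTree:
    """Propagated per-node scores for one sample; root fixed at 1.0."""

    sample_id: str
    node_scores: dict[str, float]

    def score(self, code: str) -> float:
        return self.node_scores[code]


@dataclass
class CallResult:
    sample_id: str
    called_path: list[str]  # empty == no call
    call_score: float
    top1_major: str
    top2_majors: tuple[str, str]
    threshold_used: float

    @property
    def is_call(self) -> bool:
        return bool(self.called_path)

    @property
    def called_code(self) -> str:
        return self.called_path[-1] if self.called_path else NO_CALL


def propagate(
    branch_outputs: dict[str, dict[str, float]],
    h: LabelHierarchy,
    sample_id: str = "",
) -> ScoreTree:
    """Multiply branch probabilities down the hierarchy.

    ``branch_outputs`` maps each branch parent to its child probability map.
    A missing branch is scored uniformly; a single-child node passes the
    parent score through unchanged.  Raises ``ValueError`` if a supplied
    branch vector does not sum to 1 within 1e-4 or has a negative entry.
    """
    scores: dict[str, float] = {h.root_code: 1.0}
    stack = [h.root_code]
    while stack:
        code = stack.pop()
        kids = h.children(code)
        if not kids:
            continue
        if len(kids) == 1:
            scores[kids[0]] = scores[code]  # pass-through: softmax over 1 label
            stack.append(kids[0])
            continue
        out = branch_outputs.get(code)
        if out is None:
            out = {c: 1.0 / len(kids) for c in kids}
        else:
            if set(out) != set(kids):
                raise ValueError(
                    f"branch {code!r}: output labels {sorted(out)} != children {sorted(kids)}"
                )
            total = sum(out.values())
            if abs(total - 1.0) > _SUM_TOL:
                raise ValueError(f"branch {code!r}: scores sum to {total}, not 1")
            if min(out.values()) < 0:
                raise ValueError(f"branch {code!r}: negative score")
        for child in kids:
            scores[child] = scores[code] * out[child]
            stack.append(child)
    return ScoreTree(sample_id=sample_id, node_scores=scores)


def call(tree: ScoreTree, h: LabelHierarchy, threshold: float = 0.55) -> CallResult:
    """Threshold the score tree into a (possibly empty) called path.

    Greedy descent from the root, at each level following the highest-scoring
    child (ties broken lexicographically); the called path is the prefix of
    visited nodes whose score is >= ``threshold`` (inclusive).  If the best
    major is below threshold the result is a no-call.  Top-1/top-2 majors are
    reported regardless of call status.
    """
    if threshold <= 0.5:
        raise ValueError(
            "call threshold must exceed 0.5; otherwise two sibling majors "
            "could both be called simultaneously"
        )
    majors = sorted(h.majors, key=lambda c: (-tree.node_scores[c], c))
    top1 = majors[0]
    top2 = (majors[0], majors[1]) if len(majors) > 1 else (majors[0], majors[0])

    path: list[str] = []
    code = h.root_code
    while True:
        kids = h.children(code)
        if not kids:
            break
        best = min(kids, key=lambda c: (-tree.node_scores[c], c))
        if tree.node_scores[best] < threshold:
            break
        path.append(best)
        code = best
    score = tree.node_scores[path[-1]] if path else tree.node_scores[top1]
    return CallResult(
        sample_id=tree.sample_id,
        called_path=path,
        call_score=score,
        top1_major=top1,
        top2_majors=top2,
        threshold_used=threshold,
    )
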