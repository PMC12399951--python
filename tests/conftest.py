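import numpy as np
import pytest

from oncotoc import LabelHierarchy


@pytest.fixture
def toy_h():
    """root -> {A, B}; A -> {A1, A2}; A1 -> {A1a, A1b}."""
    from oncotoc import toy_hierarchy

    return toy_hierarchy()


@pytest.fixture
def small_h():
    """3 major categories, each with 2 subcategories (the standard test
    topology: 4 branches — root + 3 majors)."""
    return make_small_hierarchy()


def make_small_hierarchy() -> LabelHierarchy:
    recs = [{"code": "root", "name": "Tissue", "parent": None, "reportable": False}]
    for major, subs in [("MA", ["MA1", "MA2"]), ("MB", ["MB1", "MB2"]), ("MC", ["MC1", "MC2"])]:
        recs.append({"code": major, "name": major, "parent": "root"})
        recs.extend({"code": s, "name": s, "parent": major} for s in subs)
    return LabelHierarchy.from_records(recs)


def random_hierarchy(rng: np.random.Generator, max_depth: int = 3, max_nodes: int = 30) -> LabelHierarchy:
    """Random rooted tree: each node gets 0-3 children until limits hit."""
    recs = [{"code": "n0", "name": "root", "parent": None, "reportable": False}]
    frontier = [("n0", 0)]
    count = 1
    while frontier and count < max_nodes:
        code, depth = frontier.pop(0)
        if depth >= max_depth:
            continue
        n_children = int(rng.integers(0, 4))
        if depth == 0:
            n_children = max(n_children, 2)  # keep at least two majors
        for _ in range(min(n_children, max_nodes - count)):
            child = f"n{count}"
            recs.append({"code": child, "name": child, "parent": code})
            frontier.append((child, depth + 1))
            count += 1
    return LabelHierarchy.from_records(recs)


def random_branch_outputs(h: LabelHierarchy, rng: np.random.Generator) -> dict:
    """Valid (Dirichlet) probability vectors for every branch of ``h``."""
    out = {}
    for branch in h.branches():
        p = rng.dirichlet(np.ones(len(branch.child_codes)))
        out[branch.parent_code] = dict(zip(branch.child_codes, p.tolist()))
    return out


def random_path(h: LabelHierarchy, rng: np.random.Generator) -> list:
    codes = [c for c in h.nodes if c != h.root_code]
    return h.path_to_root(codes[int(rng.integers(len(codes)))])
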