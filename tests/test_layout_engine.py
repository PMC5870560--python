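"""Container composition: classification, ordering, anchoring, caps, modes."""
import json

import numpy as np
import pytest

from dynatrack import (
    Classification,
    ContractViolationError,
    GenomicWindow,
    LayoutState,
    apply_pending,
    build_index,
    classify,
    compose_layout,
    load_registry,
    parse_window,
    rotate,
    summarize,
)
from dynatrack.layout_engine import GroupClassification

from conftest import make_registry_in_memory, write_deployment

W = GenomicWindow(chrom="chr1", start=0, end=1000)


def manual_classification(registry, window=W, **interesting_by_group):
    """Build a Classification by hand (rank order preserved per group)."""
    per_group = {}
    for g in registry.groups:
        if g.mode == "disabled":
            continue
        chosen = interesting_by_group.get(g.id, [])
        per_group[g.id] = GroupClassification(
            interesting=tuple(t for t in g.members if t in chosen),
            empty=tuple(t for t in g.members if t not in chosen),
        )
    return Classification(window=window, per_group=per_group)


class TestClassify:
    def test_seven_track_walkthrough_partition(self, seven_track_registry):
        idx = build_index(seven_track_registry)
        w2 = parse_window("chr2R:8878094-8896750")
        cls = classify(seven_track_registry, idx, w2)
        g = cls.per_group["g1"]
        assert g.interesting == ("t2", "t4", "t7")
        assert g.empty == ("t1", "t3", "t5", "t6")

    def test_empty_contig_classifies_everything_empty(self, seven_track_registry):
        idx = build_index(seven_track_registry)
        cls = classify(seven_track_registry, idx,
                       GenomicWindow(chrom="chrU", start=0, end=100))
        assert cls.per_group["g1"].interesting == ()
        assert set(cls.per_group["g1"].empty) == {f"t{i}" for i in range(1, 8)}

    def test_disabled_group_absent_from_classification(self):
        reg = make_registry_in_memory(3, mode="disabled")
        cls = classify(reg, __import__("dynatrack").FeatureIndex(), W)
        assert cls.per_group == {}


class TestComposeLayout:
    def test_navigation_removes_empty_tracks(self, seven_track_registry):
        reg = seven_track_registry
        idx = build_index(reg)
        s0 = LayoutState.initial(reg)
        s1 = compose_layout(reg, classify(reg, idx, parse_window("chr2R:8794209-8812865")), s0)
        assert s1.visible_ids() == ["genes"] + [f"t{i}" for i in range(1, 8)]
        s2 = compose_layout(reg, classify(reg, idx, parse_window("chr2R:8878094-8896750")), s1)
        assert s2.visible_ids() == ["genes", "t2", "t4", "t7"]
        assert not s2.overflow["g1"] and not s2.global_overflow

    def test_all_empty_leaves_only_static_tracks(self):
        reg = make_registry_in_memory(4)
        state = compose_layout(reg, manual_classification(reg), LayoutState.initial(reg))
        assert state.visible_ids() == ["genes"]

    def test_group_cap_truncates_and_flags_overflow(self):
        reg = make_registry_in_memory(5, max_visible=2)
        cls = manual_classification(reg, g1=["t1", "t2", "t3", "t4", "t5"])
        state = compose_layout(reg, cls, LayoutState.initial(reg))
        assert state.group_block("g1") == ["t1", "t2"]
        assert state.overflow["g1"] is True
        assert state.global_overflow is False  # truncated by its own cap
        summ = summarize(cls, state)
        assert (summ.per_group["g1"].n_interesting,
                summ.per_group["g1"].n_visible,
                summ.per_group["g1"].n_hidden) == (5, 2, 3)

    def test_global_budget_allocated_in_placement_order(self, tmp_path):
        reg = write_deployment(
            tmp_path,
            {
                **{f"a{i}": {"group": "gA", "rank": i,
                             "features": [("chr1", 0, 1000)]} for i in range(1, 4)},
                **{f"b{i}": {"group": "gB", "rank": i,
                             "features": [("chr1", 0, 1000)]} for i in range(1, 4)},
            },
            groups=[{"id": "gA", "anchor": "genes"}, {"id": "gB"}],
            global_max_visible=4,
        )
        idx = build_index(reg)
        state = compose_layout(reg, classify(reg, idx, W), LayoutState.initial(reg))
        # gA (anchored on the backbone) is placed first and takes 3 slots;
        # gB gets the single remaining slot
        assert state.group_block("gA") == ["a1", "a2", "a3"]
        assert state.group_block("gB") == ["b1"]
        assert state.overflow["gB"] is True and state.global_overflow is True
        # static backbone does not count against the global budget
        assert state.visible_ids()[0] == "genes"

    def test_anchored_block_sits_right_below_its_anchor(self, tmp_path):
        reg = write_deployment(
            tmp_path,
            {
                "x1": {"group": "gX", "rank": 1, "features": [("chr1", 0, 10)]},
                "y1": {"group": "gY", "rank": 1, "features": [("chr1", 0, 10)]},
            },
            groups=[{"id": "gX", "anchor": "genes"}, {"id": "gY", "anchor": "gX"}],
            statics=[{"id": "genes", "path": "genes.bed", "position": 0},
                     {"id": "snps", "path": "genes.bed", "position": 1}],
        )
        idx = build_index(reg)
        state = compose_layout(reg, classify(reg, idx, W), LayoutState.initial(reg))
        ids = state.visible_ids()
        assert ids == ["genes", "x1", "y1", "snps"]

    def test_compose_is_idempotent(self, seven_track_registry):
        reg = seven_track_registry
        idx = build_index(reg)
        cls = classify(reg, idx, parse_window("chr2R:8794209-8812865"))
        s1 = compose_layout(reg, cls, LayoutState.initial(reg))
        s2 = compose_layout(reg, cls, s1)
        assert s1.to_json() == s2.to_json()

    def test_manual_group_keeps_block_and_parks_classification(self):
        reg = make_registry_in_memory(3, mode="manual")
        cls1 = manual_classification(reg, g1=["t1", "t2"])
        s1 = compose_layout(reg, cls1, LayoutState.initial(reg))
        assert s1.group_block("g1") == []  # nothing shown yet in manual mode
        assert s1.pending["g1"].interesting == ("t1", "t2")
        s1b = apply_pending(reg, s1, "g1")
        assert s1b.group_block("g1") == ["t1", "t2"]
        assert "g1" not in s1b.pending
        # navigating again does not touch the block, only pending
        cls2 = manual_classification(reg, g1=["t3"])
        s2 = compose_layout(reg, cls2, s1b)
        assert s2.group_block("g1") == ["t1", "t2"]
        assert s2.pending["g1"].interesting == ("t3",)
        s3 = apply_pending(reg, s2, "g1")
        assert s3.group_block("g1") == ["t3"]

    def test_disabled_group_copied_verbatim(self):
        reg = make_registry_in_memory(3, mode="disabled")
        prev = LayoutState.initial(reg)
        prev.container += [  # simulate a block left over from before disabling
            type(prev.container[0])("t2", "group:g1"),
            type(prev.container[0])("t1", "group:g1"),
        ]
        state = compose_layout(reg, Classification(window=W, per_group={}), prev)
        assert state.group_block("g1") == ["t2", "t1"]


class TestApplyPending:
    def test_fixed_point_when_pending_equals_visible(self):
        reg = make_registry_in_memory(3, mode="manual")
        cls = manual_classification(reg, g1=["t1"])
        state = apply_pending(reg, compose_layout(reg, cls, LayoutState.initial(reg)), "g1")
        state2 = compose_layout(reg, cls, state)  # same window again
        state3 = apply_pending(reg, state2, "g1")
        assert state3.group_block("g1") == ["t1"] and "g1" not in state3.pending

    def test_no_pending_is_a_noop(self):
        reg = make_registry_in_memory(2, mode="manual")
        state = LayoutState.initial(reg)
        assert apply_pending(reg, state, "g1") is state

    def test_automatic_group_is_a_contract_violation(self):
        reg = make_registry_in_memory(2, mode="automatic")
        with pytest.raises(ContractViolationError):
            apply_pending(reg, LayoutState.initial(reg), "g1")

    def test_pending_respects_group_cap(self):
        reg = make_registry_in_memory(5, mode="manual", max_visible=2)
        cls = manual_classification(reg, g1=["t1", "t2", "t3", "t4"])
        state = apply_pending(reg, compose_layout(reg, cls, LayoutState.initial(reg)), "g1")
        assert state.group_block("g1") == ["t1", "t2"]
        assert state.overflow["g1"] is True


class TestSummarize:
    def test_uncapped_group_shows_everything(self):
        reg = make_registry_in_memory(7)
        cls = manual_classification(reg, g1=[f"t{i}" for i in range(1, 8)])
        state = compose_layout(reg, cls, LayoutState.initial(reg))
        s = summarize(cls, state).per_group["g1"]
        assert (s.n_interesting, s.n_visible, s.n_hidden) == (7, 7, 0)

    def test_all_empty_counts_are_zero(self):
        reg = make_registry_in_memory(3)
        cls = manual_classification(reg)
        state = compose_layout(reg, cls, LayoutState.initial(reg))
        s = summarize(cls, state)
        assert s.per_group["g1"] == type(s.per_group["g1"])(0, 0, 0)
        assert s.total_visible == 1  # the genes backbone


class TestSerialization:
    def test_state_round_trips_through_canonical_json(self, seven_track_registry):
        reg = seven_track_registry
        idx = build_index(reg)
        state = compose_layout(
            reg, classify(reg, idx, parse_window("chr2R:8794209-8812865")),
            LayoutState.initial(reg))
        text = state.to_json()
        assert json.loads(text)["version"] == 1
        assert LayoutState.from_json(text).to_json() == text


# ---------------------------------------------------------------------------
# randomized navigation traces


def expected_order(reg, blocks):
    """Hand re-derivation of the placement rule: static backbone in position
    order, each anchored block right below its target (siblings stack in
    declaration order, chains resolve depth-first), unanchored blocks at the
    end in declaration order."""
    children: dict = {}
    roots = []
    for g in reg.groups:
        if g.anchor is None:
            roots.append(g)
        else:
            children.setdefault(g.anchor, []).append(g)
    out = []

    def emit(g):
        out.extend(blocks.get(g.id, []))
        for c in children.get(g.id, []):
            emit(c)

    for s in reg.static_tracks:
        out.append(s.id)
        for g in children.get(s.id, []):
            emit(g)
    for g in roots:
        emit(g)
    return out


def random_trace_invariants(reg, idx, rng, n_steps):
    """Drive random goto/rotate/apply steps, asserting every container
    invariant after each step.  Returns the number of steps executed."""
    chroms = sorted(idx.trees) or ["chr1"]
    state = LayoutState.initial(reg)
    cls = classify(reg, idx, GenomicWindow(chrom=chroms[0], start=0, end=1))
    state = compose_layout(reg, cls, state)
    auto = [g for g in reg.groups if g.mode == "automatic"]
    manual = [g for g in reg.groups if g.mode == "manual"]
    isolated = {g.id for g in reg.groups if g.mode in ("manual", "disabled")}
    for _ in range(n_steps):
        kind = rng.choice(["goto", "goto", "rotate", "apply"])
        before = {gid: state.group_block(gid) for gid in isolated}
        if kind == "goto":
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, 90_000))
            w = GenomicWindow(chrom=chrom, start=start,
                              end=start + int(rng.integers(1, 10_000)))
            cls = classify(reg, idx, w)
            state = compose_layout(reg, cls, state)
            # idempotence
            assert compose_layout(reg, cls, state).to_json() == state.to_json()
            # mode isolation: a navigation step never alters manual/disabled blocks
            for gid in isolated:
                assert state.group_block(gid) == before[gid]
        elif kind == "rotate" and auto:
            g = auto[int(rng.integers(0, len(auto)))]
            state = rotate(state, reg, cls, g.id)
        elif kind == "apply" and manual:
            g = manual[int(rng.integers(0, len(manual)))]
            state = apply_pending(reg, state, g.id)

        state.check_invariants(reg)  # contiguity, caps, no duplicates
        # overflow flag <=> truncation, and rank-prefix at offset 0
        for g in reg.groups:
            block = state.group_block(g.id)
            if g.mode == "automatic" and g.id in cls.per_group:
                interesting = list(cls.per_group[g.id].interesting)
                n_vis = len(set(block) & set(interesting))
                assert state.overflow[g.id] == (n_vis < len(interesting))
                if state.carousel_offset.get(g.id, 0) == 0 and block:
                    assert block == interesting[: len(block)]
        # anchoring + contiguity + stacking: the whole container must equal
        # the independently re-derived placement
        blocks = {g.id: state.group_block(g.id) for g in reg.groups}
        assert state.visible_ids() == expected_order(reg, blocks)
    return n_steps


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_random_navigation_traces_preserve_invariants(tmp_path, seed):
    from dynatrack.fixtures import FixtureSpec, generate_fixtures
    from dynatrack import load_registry_file

    spec = FixtureSpec(
        seed=seed, n_groups=4, tracks_per_group=6, features_per_track=30,
        chrom_sizes={"chr1": 100_000, "chr2": 100_000},
        feature_length_range=(100, 2000),
        group_max_visible=3, global_max_visible=8,
        mode_cycle=("automatic", "manual", "automatic", "disabled"),
    )
    out = tmp_path / f"fx{seed}"
    reg_path = generate_fixtures(spec, out)
    reg = load_registry_file(reg_path)
    idx = build_index(reg)
    rng = np.random.default_rng(seed + 1000)
    assert random_trace_invariants(reg, idx, rng, n_steps=100) == 100
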