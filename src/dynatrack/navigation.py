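"""Replayable navigation scripts: the batch surrogate for browser interaction.

A script is a JSON document ``{"steps": [...]}`` where each step is an object
with exactly one key:

* ``{"goto": "chrom:start-end"}`` — navigate: classify the window and
  recompose the container;
* ``{"rotate": "<group id>"}`` — one carousel click on that group;
* ``{"apply": "<group id>"}`` — apply a manual group's pending update.

The first step must be a ``goto`` (rotation and manual application are only
meaningful once a window has been classified).  Replaying a script writes one
canonical-JSON layout state per step plus a final summary, which is the
golden-file surface for end-to-end tests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import carousel
from .datamodel import Registry, load_registry_file, parse_window
from .errors import DynatrackError, NavigationScriptError, RegionSyntaxError
from .feature_index import build_index
from .layout_engine import (
    Classification,
    LayoutState,
    LayoutSummary,
    apply_pending,
    classify,
    compose_layout,
    summarize,
)

STEP_KINDS = ("goto", "rotate", "apply")


@dataclass(frozen=True)
class NavStep:
    kind: str  # goto | rotate | apply
    arg: str   # region string or group id


def parse_script(text: str) -> list[NavStep]:
    """Parse and validate a navigation script document."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NavigationScriptError(f"script is not valid JSON: {exc}") from exc
    steps_raw = doc.get("steps") if isinstance(doc, dict) else None
    if not isinstance(steps_raw, list) or not steps_raw:
        raise NavigationScriptError('script must be {"steps": [...]} with >= 1 step')
    steps: list[NavStep] = []
    for i, raw in enumerate(steps_raw, start=1):
        if not isinstance(raw, dict) or len(raw) != 1:
            raise NavigationScriptError(f"step {i}: must be an object with exactly one key")
        (kind, arg), = raw.items()
        if kind not in STEP_KINDS:
            raise NavigationScriptError(f"step {i}: unknown step kind {kind!r}")
        if not isinstance(arg, str) or not arg:
            raise NavigationScriptError(f"step {i}: argument must be a non-empty string")
        steps.append(NavStep(kind, arg))
    if steps[0].kind != "goto":
        raise NavigationScriptError("step 1: the first step must be a goto")
    return steps


def replay(registry: Registry, steps: list[NavStep]) -> tuple[list[LayoutState], LayoutSummary]:
    """Execute a parsed script; return the per-step states and final summary."""
    index = build_index(registry)
    state = LayoutState.initial(registry)
    classification: Classification | None = None
    states: list[LayoutState] = []
    for i, step in enumerate(steps, start=1):
        try:
            if step.kind == "goto":
                classification = classify(registry, index, parse_window(step.arg))
                state = compose_layout(registry, classification, state)
            elif step.kind == "rotate":
                assert classification is not None  # guaranteed by parse_script
                state = carousel.rotate(state, registry, classification, step.arg)
            else:  # apply
                state = apply_pending(registry, state, step.arg)
        except (DynatrackError, RegionSyntaxError) as exc:
            raise NavigationScriptError(f"step {i} ({step.kind} {step.arg}): {exc}") from exc
        states.append(state)
    assert classification is not None
    return states, summarize(classification, states[-1])


def run_navigation(registry_path: str | Path, script_path: str | Path,
                   out_dir: str | Path) -> tuple[list[Path], Path]:
    """Replay a script file, writing numbered canonical-JSON states.

    Writes ``state_001.json`` ... ``state_NNN.json`` and ``summary.json``
    under ``out_dir``; returns their paths.  Any invalid step aborts with a
    :class:`NavigationScriptError` naming the step index.
    """
    registry = load_registry_file(registry_path)
    steps = parse_script(Path(script_path).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    states, summary = replay(registry, steps)
    paths = []
    for i, st in enumerate(states, start=1):
        p = out / f"state_{i:03d}.json"
        p.write_text(st.to_json())
        paths.append(p)
    summary_path = out / "summary.json"
    summary_path.write_text(summary.to_json())
    return paths, summary_path
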