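"""Text formats, configuration and run manifests.

Scores travel as a commented TSV (header lines carry key, context and grid
metadata; rows are hand / position / pitch / finger), performances as a
keystroke TSV with trial metadata in the header, both round-tripping
losslessly.  Run configuration is YAML with every analysis toggle explicit,
and each pipeline run writes a manifest (config hash, seed, version) that
suffices to reproduce its outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .score import Performance, Score

__all__ = [
    "ScoreParseError",
    "read_score",
    "write_score",
    "read_performance",
    "write_performance",
    "RunConfig",
    "write_manifest",
    "ioi_to_bpm",
    "bpm_to_ioi",
]


class ScoreParseError(ValueError):
    def __init__(self, msg: str, line: int | None = None):
        if line is not None:
            msg = f"line {line}: {msg}"
        super().__init__(msg)


def ioi_to_bpm(ioi_ms: float, beat_sixteenths: int = 4) -> float:
    """Quarter-note beats per minute for a sixteenth-note IOI in ms."""
    return 60000.0 / (ioi_ms * beat_sixteenths)


def bpm_to_ioi(bpm: float, beat_sixteenths: int = 4) -> float:
    return 60000.0 / (bpm * beat_sixteenths)


def write_score(score: Score, path) -> None:
    lines = [
        "# rangeplan score v1",
        f"# key: {score.key_tonic} {score.key_mode}",
        f"# context: {score.context_label}",
        f"# excerpt_id: {score.excerpt_id}",
        f"# layout: pre={score.pre_len} excerpt={score.excerpt_len} post={score.post_len}",
        f"# grid: levels={score.n_levels} tactus={score.tactus_level} offset={score.grid_offset}",
    ]
    if score.final_notes:
        fn = " ".join(f"{h}={p}" for h, p in sorted(score.final_notes.items()))
        lines.append(f"# final_notes: {fn}")
    lines.append("hand\tposition\tpitch\tfinger")
    for hand in sorted(score.pitches):
        seq = score.pitches[hand]
        fingers = score.fingers[hand] if score.fingers else [""] * len(seq)
        for pos, (p, f) in enumerate(zip(seq, fingers)):
            lines.append(f"{hand}\t{pos}\t{int(p)}\t{f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_score(path) -> Score:
    meta: dict = {}
    pitches: dict = {}
    fingers: dict = {}
    header_seen = False
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if not header_seen:
            if line.split("\t")[:3] != ["hand", "position", "pitch"]:
                raise ScoreParseError("expected 'hand position pitch finger' header", ln)
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ScoreParseError(f"expected >= 3 tab-separated fields, got {len(parts)}", ln)
        hand, pos, pitch = parts[0], int(parts[1]), int(parts[2])
        finger = parts[3] if len(parts) > 3 else ""
        pitches.setdefault(hand, []).append((pos, pitch))
        fingers.setdefault(hand, []).append((pos, finger))
    if not pitches:
        raise ScoreParseError("no note rows found")
    if len(pitches) > 2:
        raise ScoreParseError(f"more than two staves/hands: {sorted(pitches)}")
    for hand, rows in pitches.items():
        positions = [p for p, _ in rows]
        if positions != list(range(len(rows))):
            raise ScoreParseError(f"hand {hand}: positions not consecutive from 0")
    key = meta.get("key", "C major").split()
    layout = dict(kv.split("=") for kv in meta.get("layout", "").split()) \
        if "layout" in meta else {}
    grid = dict(kv.split("=") for kv in meta.get("grid", "").split()) \
        if "grid" in meta else {}
    final_notes = None
    if "final_notes" in meta:
        final_notes = {kv.split("=")[0]: int(kv.split("=")[1])
                       for kv in meta["final_notes"].split()}
    return Score(
        pitches={h: np.array([p for _, p in rows]) for h, rows in pitches.items()},
        fingers={h: [f for _, f in rows] for h, rows in fingers.items()},
        context_label=meta.get("context", "long"),
        key_tonic=key[0], key_mode=key[1] if len(key) > 1 else "major",
        excerpt_id=int(meta.get("excerpt_id", 1)),
        pre_len=int(layout.get("pre", 12)),
        excerpt_len=int(layout.get("excerpt", 8)),
        n_levels=int(grid.get("levels", 4)),
        tactus_level=int(grid.get("tactus", 2)),
        grid_offset=int(grid.get("offset", 0)),
        final_notes=final_notes,
    )


_PERF_META = ["ioi_nominal_ms", "tempo_label", "participant", "excerpt_id",
              "context_label", "block", "repetition"]


def write_performance(perf: Performance, path) -> None:
    lines = ["# rangeplan performance v1"]
    for k in _PERF_META:
        lines.append(f"# {k}: {getattr(perf, k)}")
    lines.append("onset_ms\tpitch\tvelocity\thand")
    for row in perf.keystrokes.itertuples(index=False):
        lines.append(f"{row.onset_ms:.3f}\t{int(row.pitch)}\t{int(row.velocity)}\t{row.hand}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_performance(path) -> Performance:
    meta: dict = {}
    rows = []
    header_seen = False
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if not header_seen:
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ScoreParseError(f"expected 4 fields, got {len(parts)}", ln)
        rows.append(dict(onset_ms=float(parts[0]), pitch=int(parts[1]),
                         velocity=int(parts[2]), hand=parts[3]))
    ks = pd.DataFrame(rows, columns=["onset_ms", "pitch", "velocity", "hand"])
    kwargs = {}
    for k in _PERF_META:
        if k in meta:
            v = meta[k]
            kwargs[k] = (float(v) if k == "ioi_nominal_ms"
                         else int(v) if k in ("participant", "excerpt_id",
                                              "block", "repetition")
                         else v)
    return Performance(keystrokes=ks, **kwargs)


@dataclass
class RunConfig:
    """All pipeline settings, each defaulting to the analysis-faithful choice."""

    seed: int = 0
    n_participants: int = 26
    window: int = 8
    chord_window_ms: float = 94.0
    tempo_ms: dict = field(default_factory=lambda:
                           {"fast": 187.5, "medium": 225.0, "slow": 429.0})
    # model bounds
    a_bounds: tuple = (0.8, 1.0)
    w2_bounds: tuple = (0.25, 0.99)
    # documented design-decision toggles
    chance_multiset: bool = True          # intruders from the pitch multiset
    chance_apply_exclusions: bool = False  # chance errors are not filtered
    predicted_interior_only: bool = False  # keep edge-clipped positions
    include_deletions_in_rates: bool = True
    grid_offset: int = 0                   # metrical phase of position 0
    include_learning: bool = True

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["a_bounds"] = list(d["a_bounds"])
        d["w2_bounds"] = list(d["w2_bounds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["a_bounds"] = tuple(d["a_bounds"])
        d["w2_bounds"] = tuple(d["w2_bounds"])
        return cls(**d)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(path, config: RunConfig, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {"config_sha256": config.digest(), "seed": config.seed,
                "rangeplan_version": __version__}
    manifest.update(extra or {})
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))
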