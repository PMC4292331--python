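"""Minimal Standard MIDI File reading and writing.

Covers exactly what keyboard-performance capture needs: format 0/1 files,
one or two tracks, tempo meta events, note-on/note-off with running
status, and velocity preservation.  A note-on with velocity 0 is a
note-off, per the MIDI standard.  Channels map to hands (0 = right,
1 = left) when a file is read back into a keystroke table.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_midi", "read_midi", "MidiParseError"]

_TPQ = 480  # ticks per quarter note
_CHANNEL_HAND = {0: "R", 1: "L"}
_HAND_CHANNEL = {"R": 0, "L": 1}


class MidiParseError(ValueError):
    """Malformed Standard MIDI File."""

    def __init__(self, msg: str, offset: int | None = None):
        if offset is not None:
            msg = f"{msg} (byte offset {offset})"
        super().__init__(msg)


def _vlq(value: int) -> bytes:
    """Encode a variable-length quantity."""
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _read_vlq(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        if pos >= len(data):
            raise MidiParseError("truncated variable-length quantity", pos)
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, pos


def write_midi(keystrokes: pd.DataFrame, path, note_ms: float = 150.0,
               bpm: float | None = None) -> None:
    """Write a keystroke table as a format-1 Standard MIDI File.

    ``keystrokes`` needs columns ``onset_ms``, ``pitch``, ``velocity`` and
    ``hand``; each hand becomes one track on its own channel.  Notes are
    given a fixed sounding duration of ``note_ms`` (the stimuli are
    isochronous keystrokes, not sustained voices).
    """
    us_per_quarter = int(round(60e9 / bpm / 1000)) if bpm else 500000
    ms_per_tick = us_per_quarter / 1000.0 / _TPQ

    hands = [h for h in ("R", "L") if (keystrokes["hand"] == h).any()]
    chunks = []
    # track 0: tempo map
    tempo = (b"\x00\xff\x51\x03" + struct.pack(">I", us_per_quarter)[1:]
             + b"\x00\xff\x2f\x00")
    chunks.append(b"MTrk" + struct.pack(">I", len(tempo)) + tempo)
    for hand in hands:
        ch = _HAND_CHANNEL[hand]
        sub = keystrokes[keystrokes["hand"] == hand]
        events = []  # (tick, order, status, pitch, velocity)
        for row in sub.itertuples(index=False):
            on = int(round(row.onset_ms / ms_per_tick))
            off = int(round((row.onset_ms + note_ms) / ms_per_tick))
            events.append((on, 1, 0x90 | ch, int(row.pitch), int(row.velocity)))
            events.append((off, 0, 0x80 | ch, int(row.pitch), 0))
        events.sort()
        payload = bytearray()
        clock = 0
        for tick, _, status, pitch, velocity in events:
            payload += _vlq(tick - clock)
            payload += bytes([status, pitch, velocity])
            clock = tick
        payload += b"\x00\xff\x2f\x00"
        chunks.append(b"MTrk" + struct.pack(">I", len(payload)) + bytes(payload))
    header = b"MThd" + struct.pack(">IHHH", 6, 1, len(chunks), _TPQ)
    Path(path).write_bytes(header + b"".join(chunks))


def read_midi(path) -> pd.DataFrame:
    """Read note-on events of a format 0/1 file into a keystroke table.

    Returns columns ``onset_ms``, ``pitch``, ``velocity``, ``hand``
    (channel 0 -> "R", channel 1 -> "L", others -> "").  Note-ons with
    velocity 0 are treated as note-offs and do not produce keystrokes.
    """
    data = Path(path).read_bytes()
    if data[:4] != b"MThd":
        raise MidiParseError("missing MThd header", 0)
    hlen, fmt, ntrk, division = struct.unpack(">IHHH", data[4:14])
    if fmt not in (0, 1):
        raise MidiParseError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise MidiParseError("SMPTE time division is not supported")
    pos = 8 + hlen
    tempo_us = 500000  # default 120 bpm
    rows = []
    for _ in range(ntrk):
        if data[pos:pos + 4] != b"MTrk":
            raise MidiParseError("missing MTrk chunk", pos)
        tlen = struct.unpack(">I", data[pos + 4:pos + 8])[0]
        tpos, tend = pos + 8, pos + 8 + tlen
        pos = tend
        tick = 0
        status = None
        while tpos < tend:
            delta, tpos = _read_vlq(data, tpos)
            tick += delta
            b = data[tpos]
            if b >= 0x80:
                status = b
                tpos += 1
            elif status is None:
                raise MidiParseError("running status without prior status", tpos)
            if status == 0xFF:  # meta
                mtype = data[tpos]
                mlen, tpos = _read_vlq(data, tpos + 1)
                if mtype == 0x51:
                    tempo_us = int.from_bytes(data[tpos:tpos + 3], "big")
                tpos += mlen
            elif status in (0xF0, 0xF7):  # sysex
                mlen, tpos = _read_vlq(data, tpos)
                tpos += mlen
            else:
                kind = status & 0xF0
                nbytes = 1 if kind in (0xC0, 0xD0) else 2
                payload = data[tpos:tpos + nbytes]
                tpos += nbytes
                if kind == 0x90 and payload[1] > 0:
                    ms = tick * tempo_us / 1000.0 / division
                    rows.append(dict(
                        onset_ms=ms, pitch=int(payload[0]),
                        velocity=int(payload[1]),
                        hand=_CHANNEL_HAND.get(status & 0x0F, "")))
    df = pd.DataFrame(rows, columns=["onset_ms", "pitch", "velocity", "hand"])
    return df.sort_values("onset_ms", kind="stable").reset_index(drop=True)
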