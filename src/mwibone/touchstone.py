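"""Minimal Touchstone one-port (.s1p) reader/writer.

Supports the RI (real/imaginary) and MA (magnitude/angle-in-degrees) data
formats and Hz/kHz/MHz/GHz frequency units. Only S-parameter one-port files
are handled; anything else raises.
"""

from __future__ import annotations

import numpy as np

_UNIT_SCALE = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}


def read_s1p(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a one-port Touchstone file.

    Returns ``(frequencies_hz, gamma)`` with gamma complex.
    """
    scale = 1e9  # Touchstone default unit is GHz
    fmt = "MA"  # Touchstone default format
    freqs: list[float] = []
    vals: list[complex] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                tokens = line[1:].upper().split()
                for i, tok in enumerate(tokens):
                    if tok in _UNIT_SCALE:
                        scale = _UNIT_SCALE[tok]
                    elif tok in ("RI", "MA", "DB"):
                        fmt = tok
                    elif tok == "S":
                        pass
                    elif tok == "R":
                        break  # reference impedance follows; ignore value
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed Touchstone data line: {raw!r}")
            f, a, b = (float(p) for p in parts[:3])
            freqs.append(f * scale)
            if fmt == "RI":
                vals.append(complex(a, b))
            elif fmt == "MA":
                vals.append(a * np.exp(1j * np.deg2rad(b)))
            else:  # DB
                vals.append(10 ** (a / 20.0) * np.exp(1j * np.deg2rad(b)))
    if not freqs:
        raise ValueError(f"no data rows found in {path}")
    return np.asarray(freqs, dtype=float), np.asarray(vals, dtype=complex)


def write_s1p(path, frequencies_hz, gamma, fmt: str = "RI", comment: str | None = None) -> None:
    """Write a one-port Touchstone file (Hz units)."""
    frequencies_hz = np.asarray(frequencies_hz, dtype=float)
    gamma = np.asarray(gamma, dtype=complex)
    if frequencies_hz.shape != gamma.shape:
        raise ValueError("frequency and gamma arrays must have the same shape")
    fmt = fmt.upper()
    if fmt not in ("RI", "MA"):
        raise ValueError(f"unsupported format {fmt!r}")
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"! {line}\n")
        fh.write(f"# HZ S {fmt} R 50\n")
        for f, g in zip(frequencies_hz, gamma):
            if fmt == "RI":
                fh.write(f"{f:.6f} {g.real:.12g} {g.imag:.12g}\n")
            else:
                fh.write(f"{f:.6f} {abs(g):.12g} {np.rad2deg(np.angle(g)):.12g}\n")
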