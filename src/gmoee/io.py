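"""Reading and writing univariate samples as plain text / single-column CSV."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import Sample


def read_sample(path, label: str | None = None) -> Sample:
    """Read a positive univariate sample from a text file.

    Accepted layout: one numeric value per line, or a single-column CSV
    with an optional non-numeric header line; lines starting with ``#``
    are comments.  Values are validated strictly positive.
    """
    path = Path(path)
    values = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip().rstrip(",")
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line))
            except ValueError:
                if lineno == 1 or (not values and lineno <= 2):
                    continue  # header line
                raise ValueError(f"{path}:{lineno}: not a number: {line!r}")
    if not values:
        raise ValueError(f"{path}: no numeric values found")
    return Sample(values=np.asarray(values), label=label or path.name)


def write_sample(sample: Sample, path, header: str | None = None) -> None:
    """Write a sample one value per line, with an optional ``#`` header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for v in sample.values:
            fh.write(f"{v:.17g}\n")
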