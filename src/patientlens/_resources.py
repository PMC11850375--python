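"""Access to packaged data files (name lists, fixture lexicons, templates)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


def data_path(name: str):
    """Return a traversable handle on a packaged data file."""
    return resources.files("patientlens.data").joinpath(name)


def read_text(name: str) -> str:
    return data_path(name).read_text(encoding="utf-8")


@lru_cache(maxsize=None)
def read_lines(name: str) -> tuple[str, ...]:
    """Non-empty, non-comment lines of a packaged text file."""
    out = []
    for line in read_text(name).splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return tuple(out)
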