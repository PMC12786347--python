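"""Named parameter presets shipped as YAML data files.

Presets are plain mappings; feed them to the matching parameter
dataclass, e.g. ``BEIParams(**load_preset("bei_deco2014"))``.
"""

from importlib import resources

import yaml

_PACKAGE = __name__


def available_presets():
    """Names of the shipped presets."""
    root = resources.files(_PACKAGE)
    return sorted(p.name[:-5] for p in root.iterdir()
                  if p.name.endswith(".yaml"))

def load_preset(name: str) -> dict:
    """Load a named preset as a plain dict."""
    root = resources.files(_PACKAGE)
    path = root / f"{name}.yaml"
    if not path.is_file():
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{available_presets()}")
    with path.open("r") as fh:
        return yaml.safe_load(fh)
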