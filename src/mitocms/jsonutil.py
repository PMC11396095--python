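"""JSON serialization that tolerates numpy scalar types."""

import json

import numpy as np


def _default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def dumps(obj, **kwargs) -> str:
    kwargs.setdefault("default", _default)
    return json.dumps(obj, **kwargs)
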