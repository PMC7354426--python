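"""Regenerate the packaged reference-characteristic JSON fixtures.

Run from the repository root:

    python scripts/regenerate_fixtures.py

Rebuilds src/spiderstat/data/<name>.json from the recipes recorded in
spiderstat.fixtures (noiseless calibrated bench + seeded fit), so the
packaged files are reproducible bit-exactly.
"""

import json
from pathlib import Path

from spiderstat.fixtures import REFERENCE_NAMES, reference_fixture_dict

DATA_DIR = Path(__file__).resolve().parent.parent / "src" / "spiderstat" / "data"


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    for name in REFERENCE_NAMES:
        payload = reference_fixture_dict(name)
        out = DATA_DIR / f"{name}.json"
        out.write_text(json.dumps(payload, indent=1) + "\n")
        print(f"wrote {out} (r_squared={payload['r_squared']:.8f})")


if __name__ == "__main__":
    main()
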