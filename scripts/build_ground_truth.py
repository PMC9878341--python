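"""Regenerate the packaged ground-truth network.

Runs the deterministic construction + calibration pipeline and freezes the
result into src/prediabn/data/ground_truth_network.json.  Maintenance
tool; the shipped JSON is the committed output of this script.
"""

import json
import sys
from pathlib import Path

from prediabn.calibration import calibration_report
from prediabn.cohort import calibrate_ground_truth, calibration_targets

OUT = Path(__file__).resolve().parent.parent / "src" / "prediabn" / "data" / "ground_truth_network.json"


def main() -> int:
    trace: list = []
    net = calibrate_ground_truth(trace=trace)
    report = calibration_report(net, calibration_targets())
    print(report.to_string())
    if not report.met.all():
        print("calibration incomplete; not writing", file=sys.stderr)
        return 1
    OUT.write_text(json.dumps(net.to_dict(), indent=None, separators=(",", ":")), encoding="utf-8")
    print(f"wrote {OUT} ({OUT.stat().st_size} bytes, {len(trace)} accepted steps)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
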