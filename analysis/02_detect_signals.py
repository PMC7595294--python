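#!/usr/bin/env python
"""Detect and classify signals in the demo recording; score against truth.

Reads results/demo/recording.wav (run 01_simulate_recordings.py first),
writes detected events and the per-recording summary, and prints per-class
precision/recall/F1 against the generator's annotations.
"""

import json
from pathlib import Path

from hivesignals import (
    ESFRecording,
    detect_recording,
    evaluate_detector,
    read_annotations,
    write_annotations,
)

DEMO = Path(__file__).resolve().parents[1] / "results" / "demo"


def main() -> None:
    recording = ESFRecording.from_wav(DEMO / "recording.wav")
    truth = read_annotations(DEMO / "annotations.csv")
    result = detect_recording(recording)
    write_annotations(result.events, DEMO / "detected.csv")
    (DEMO / "summary.json").write_text(result.to_json())
    print("summary:", json.dumps(result.summary.to_dict(), indent=2))
    scores = evaluate_detector(truth, result.events, match_iou=0.5)
    for behavior in ("waggle_run", "fanning", "stop_signal"):
        s = scores[behavior]
        print(f"{behavior:12s} P={s['precision']:.2f} R={s['recall']:.2f} F1={s['f1']:.2f}")


if __name__ == "__main__":
    main()
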