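"""Real-time style detection on a sliding 30 s buffer shifted by 10 s.

Feeds a record through the streaming detector in 1 s blocks, as a wearable
would deliver it, and compares against whole-record batch detection. The
buffer variance is recomputed per buffer, so normalized power — and with it
marginal threshold decisions — can differ slightly between the two modes.
"""

from swdetect import DetectorParams, SynthConfig, gen_record, run_detection

record = gen_record(SynthConfig(duration=300.0, n_seizures=2, seed=12))
p = DetectorParams()

batch = run_detection(record, p, mode="batch")
stream = run_detection(record, p, mode="stream", buffer_duration=30.0, shift=10.0)

print("true seizures: ", [(round(s, 1), round(e, 1)) for s, e in record.reference_events])
print("batch events:  ", [(round(e.start, 1), round(e.end, 1)) for e in batch])
print("stream events: ", [(round(e.start, 1), round(e.end, 1)) for e in stream])
print("\nStreaming timestamps are absolute; events recurring in overlapping "
      "buffers were merged into one episode each.")
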