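"""Simulate a single-option oddball session and inspect its structure.

Builds one cartoon-face session with 5 symbols and the protocol's
timing (75 ms flash + 75 ms gap, ~30 s stimulation blocks, >= 280
target flashes), then prints the event bookkeeping and writes the
session to a BIDS-style folder and reads it back.
"""

import tempfile

from p300decode import SimulationConfig, read_session, simulate_session, write_session

config = SimulationConfig(n_symbols=5, condition="CF", min_target_flashes=280, seed=1)
rec = simulate_session(config)

flashes = rec.labelled_events
n_target = (flashes["label"] == "target").sum()
n_nontarget = (flashes["label"] == "nontarget").sum()
print(f"channels: {rec.channel_names}")
print(f"duration: {rec.n_samples / rec.sampling_rate:.0f} s at {rec.sampling_rate:g} Hz")
print(f"blocks: {rec.events['block_id'].nunique()}")
print(f"target flashes: {n_target}, non-target flashes: {n_nontarget}")
print(f"identity N_nontarget = N_target * (N_symbols - 1): "
      f"{n_nontarget} == {n_target} * {config.n_symbols - 1}")

with tempfile.TemporaryDirectory() as root:
    paths = write_session(rec, root)
    print(f"\nwrote {len(paths)} files (BrainVision + channels/events TSV + sidecar)")
    back = read_session(root, "01", "01", "CF")
    print(f"read back: {len(back.events)} events, condition {back.condition}, "
          f"{back.n_symbols} symbols")

# The counts demonstrate the oddball design: the attended symbol is rare
# (1 in n_symbols), which is what elicits the P300 response.
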