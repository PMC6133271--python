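"""Generate a synthetic grooming log and pair role-reversed events.

Each pair is an (X, Y, Delta) triple: X seconds of grooming answered by Y
seconds, with a signed gap Delta between the end of the first event and the
start of the reply (negative = mutual grooming).
"""

from deltagroom import SynthConfig, generate, pair_events, summarize_log
from deltagroom.pairing import WITHIN_BOUT, delta_summary

log = generate(SynthConfig(seed=42))
summary = summarize_log(log)
print(f"events: {summary['n_events']}")
print(f"observation hours: {summary['total_observation_hours']:.1f}")
print(f"groomed (chimpanzee-)hours: {summary['total_groomed_hours']:.1f}")
print(f"active dyads: {summary['n_active_dyads']} of {summary['n_possible_dyads']}")

pairs = pair_events(log)
n_within = sum(p.condition == WITHIN_BOUT for p in pairs)
print(f"\npairs: {len(pairs)} ({n_within} within-bout, {len(pairs) - n_within} delayed)")

d = delta_summary(pairs)
print(f"Delta range: {d['min_delta_min']:.1f} to {d['max_delta_min']:.1f} minutes")
# A within-bout pair (Delta < 0) means the reply began during the original
# grooming; a wide positive range shows reciprocation can come much later.
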