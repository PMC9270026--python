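"""Build the deprivation protocols and inspect their structure.

The full ultradian protocol repeats 2.5 h of stimulation + 4.5 h of
rebound every 7 h; because gcd(7, 24) = 1 the rebound onset visits every
hour of the day across 24 episodes.  The abridged protocol stimulates
five times so that rebound lands at two morning and three evening
clock positions.
"""

from flysleep import make_abridged_ssd, make_full_ssd, stimulus_times, validate_schedule

full = make_full_ssd()
print(f"full protocol: {full.n_episodes} episodes, "
      f"onsets {', '.join(f'{z:.1f}' for z in full.onset_zts[:6])}, ...")
print(f"  hour classes covered: {len({int(z) for z in full.onset_zts})}/24")
print(f"  valid: {validate_schedule(full).ok}")

abridged = make_abridged_ssd()
print(f"abridged protocol: {abridged.n_episodes} episodes, "
      f"onsets {sorted(abridged.onset_zts)}")

onsets = stimulus_times(full.episodes[0], seed=0, jitter_s=5.0)
print(f"episode 0 stimulus train: {len(onsets)} pulses, "
      f"mean interval {(onsets[1:] - onsets[:-1]).mean():.1f} s")
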