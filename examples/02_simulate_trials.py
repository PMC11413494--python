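"""Generate a synthetic simulated-strike trial table.

Each row is one animal's single encounter with the spring-loaded strike
simulator: it jumps or scrambles with a species-specific propensity, and
its timing and jump-performance values are drawn from the per-species field
distributions, digitized to the video frame grid and censored at
field-realistic rates.
"""

from escapekin import default_censoring, default_profiles, generate_trials, jump_frequency

profiles = default_profiles()
trials = generate_trials(
    profiles, n_per_species=50, censoring=default_censoring(), seed=42
)

print(f"{len(trials)} trials, one per individual\n")
print(trials.head(5).to_string(index=False))

print("\njump frequency per species (jumps/trials, percent):")
print(jump_frequency(trials).to_string(index=False))
print(
    "\nKangaroo rats and pocket mice jump in most trials; woodrats (NEAL)"
    "\nand ground squirrels (OTBE) almost always scramble instead."
)
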