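"""Choosing the k-mer length by presence/absence entropy.

For each candidate K, every distinct canonical k-mer contributes the
binary entropy of its presence fraction across species; the average is
low when K is so short that every k-mer occurs everywhere, and low
again when K is so long that every k-mer is private to one species.
The selected K is the interior maximum.
"""

from kmerphylo import SimulationConfig, entropy_profile, evolve_sequences

records = evolve_sequences(
    SimulationConfig(
        tree="(A:0.1,B:0.1,C:0.1,D:0.1,E:0.1);", root_length=10_000, seed=42
    )
)
profile = entropy_profile(records, K_min=6, K_max=18)
print(profile.table.to_string(index=False,
                              formatters={"average_entropy": "{:.4f}".format}))
print(f"\nselected K = {profile.selected_K} "
      "(m = distinct canonical k-mers; entropy in bits, averaged over them)")
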