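"""Oligomeric state from mass photometry.

Draws 5,000 event masses from the full-length-probe preset (85% dimer
at 181 kD, 15% monomer at 92 kD), decomposes the distribution by a
seeded Gaussian-mixture fit, and shows that BIC picks two populations.
"""

from phagoflux.massphot import fit_mass_mixture, select_components
from phagoflux.simulate import MASS_PRESETS, generate_mass_events

masses = generate_mass_events(MASS_PRESETS["snxa_full_length"], seed=1)
best_k, bics = select_components(masses, k_range=(1, 2, 3), seed=1)
print(f"events: {masses.size};  BIC prefers k = {best_k} "
      f"({', '.join(f'k={k}: {b:.0f}' for k, b in bics.items())})")

components, _ = fit_mass_mixture(masses, k=2, seed=1)
for c in components:
    note = "  [below the reliable mass range]" if c.low_mass_flag else ""
    print(f"  {100 * c.fraction:5.1f}%  {c.mean:6.1f} ± {c.sd:4.1f} kD{note}")
# The heavier population's fraction and mean should recover the preset
# (85%, 181 kD) within the sampling error of 5,000 events.  Apparent
# masses below ~100 kD are flagged as outside the instrument's
# reliable range for native proteins.
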