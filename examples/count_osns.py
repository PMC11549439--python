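"""The stereological counting chain on the study's measured inputs.

Runs the five-step extrapolation: linear OSN density and epithelial
thickness combine into a volumetric density (Fieller SEM), which is
extrapolated over the olfactory-epithelium envelope volume to a total count
with a Delta-method 90 % confidence interval; sphere-model glomerulus
estimates and convergence ratios follow.
"""

from olfrecon.morphometry import (
    LinearDensity,
    ThicknessEstimate,
    epithelium_surface_area,
    ratio_report,
    sphere_glomerulus_count,
    total_osn,
    volumetric_density,
)

# measured inputs: OSNs per mm of epithelium, epithelial thickness (um),
# envelope volume (mm^3), glomerular volumes (mm^3)
lin = LinearDensity(mean=78.31, sem=4.65)
thick = ThicknessEstimate(mean=67.23, sem=0.90)
envelope_mm3 = 22.97
glom_left, glom_right = 1.55, 1.34

density = volumetric_density(lin, thick, section_thickness_um=10.0)
total = total_osn(density, envelope_mm3)
area = epithelium_surface_area(envelope_mm3, thick)

print(f"OSN density      : {density.mean:,.2f} +/- {density.sem:,.2f} per mm^3")
print(f"total OSNs       : {total.mean:,.0f} +/- {total.sem:,.0f}")
print(f"90% CI           : {total.ci90[0]:,.0f} .. {total.ci90[1]:,.0f}")
print(f"epithelium area  : {area.mean:.1f} mm^2")

print("\nsphere-model glomerulus counts (left / right):")
for d in (59.60, 55.15, 65.13):
    left = sphere_glomerulus_count(glom_left, d).count
    right = sphere_glomerulus_count(glom_right, d).count
    print(f"  diameter {d:5.2f} um : {left:6,d} / {right:6,d}")

n_glom = (sphere_glomerulus_count(glom_left, 59.60).count
          + sphere_glomerulus_count(glom_right, 59.60).count)
ratios = ratio_report(total.mean, n_glom, n_genes=389)
print(f"\nOSNs per glomerulus         : ~{ratios['osns_per_glomerulus_rounded']}")
print(f"OSNs per odorant-receptor gene: {ratios['osns_per_gene_rounded']:,}")
# The total is ~2.7 million OSNs; each glomerulus receives on the order of
# a hundred axons, an order of magnitude fewer than the ~917 in mice.
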