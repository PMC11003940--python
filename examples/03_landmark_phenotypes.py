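"""Extract the full landmark phenotype battery for a few individuals.

Distances (straight-line, city-block, on-surface geodesic), curvatures,
proportion indices, angles, triangle areas, and region hull volumes/areas —
the per-individual phenotype families derived from 26 landmarks and the
facial surface.
"""

from facedissect import PopulationModel, build_template, simulate_population
from facedissect.landmark_phenotypes import extract_phenotypes

template = build_template(41)
sample = simulate_population(template, PopulationModel(), n_per_region=1, seed=3)

sets = [ind.true_landmarks for ind in sample.individuals]
meshes = [ind.mesh for ind in sample.individuals]
matrix = extract_phenotypes(sets, meshes)

print(f"{matrix.n_individuals} individuals x {matrix.n_phenotypes} phenotypes")
print(matrix.metadata["category"].value_counts().to_string())

row = matrix.values.iloc[0]
eu = row["Euclidean:endocanthion_l|endocanthion_r"]
geo = row["Geodesic:endocanthion_l|endocanthion_r"]
print(f"\nintercanthal width: Euclidean {eu:.1f} mm, geodesic {geo:.1f} mm")
print("(the on-surface path over the nasal root is always at least the chord)")
print(f"mean curvature at pronasale: {row['Curvature:MC.pronasale']:.3f} 1/mm "
      "(positive = convex nose tip)")
print(f"nose hull volume: {row['Volume:nose']:.0f} mm^3")
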