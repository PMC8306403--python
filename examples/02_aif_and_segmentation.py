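"""Render a phantom, extract the AIF and segment the perfused tumour.

Shows the image-side pipeline on a small noiseless scene with a rimmed
lesion: relative enhancement, the 95th-percentile aorta refinement, the
maximum-enhancement map and the percentage-threshold segmentation.
"""

from dcekin import (
    AcquisitionSpec,
    LesionSpec,
    PhantomScene,
    extract_aif,
    max_enhancement_map,
    refine_aif_roi,
    relative_enhancement,
    render_phantom,
    threshold_perfused_roi,
)
from dcekin.phantom import AortaSpec

scene = PhantomScene(
    grid_shape=(24, 24, 10),
    acquisition=AcquisitionSpec(n_dynamic=60),
    aorta=AortaSpec(centre_xy=(5, 5), radius=2.5),
    lesions=(
        LesionSpec(centre=(16, 12, 5), radius=3.0, ktrans_true=0.8, ecv_true=35.0,
                   rim_width=1, rim_scale=0.5),
    ),
    noise_sd=0.0,
)
series, masks, truth = render_phantom(scene)
enh = relative_enhancement(series)

refined = refine_aif_roi(masks["aorta"], enh)
aif = extract_aif(refined, enh)
print(f"aorta: {masks['aorta'].n_voxels} candidate voxels -> "
      f"{refined.n_voxels} in the 95th-100th percentile band; "
      f"AIF peak enhancement = {aif.values.max():.2f}")

emap = max_enhancement_map(enh)
roi = threshold_perfused_roi(masks["lesion_0"], emap, fraction=0.6,
                             voxel_volume=series.voxel_volume)
print(f"lesion: {masks['lesion_0'].n_voxels} candidate voxels "
      f"(core + half-enhancing rim) -> {roi.n_voxels} perfused voxels, "
      f"volume = {roi.perfused_volume_cm3:.2f} cm^3 "
      f"(true core volume = {truth['volume_true_cm3'].iloc[0]:.2f} cm^3)")
# At a 0.6 fractional threshold the half-amplitude rim is excluded, so the
# perfused ROI reproduces the generating core exactly.
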