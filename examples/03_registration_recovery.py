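"""Recover planted transforms: affine translation/rotation and a smooth
deformation, measured against the known ground truth."""

import numpy as np

from cyclereg import (AffineTransform, DeformationField, PhantomParams,
                      affine_register, demons_register, endpoint_error,
                      field_from_affine, make_paired_case, warp)

case = make_paired_case(PhantomParams(seed=2))
img = case.image_ct

# plant a (5, 3)-pixel translation
d = np.zeros(img.shape + (2,)); d[:, :, 0], d[:, :, 1] = 5.0, 3.0
moving = warp(img, DeformationField(d, img.spacing))
a = affine_register(img, moving)
rec = np.asarray(a.translation) / np.asarray(img.spacing)
print(f"planted translation (5, 3) px -> recovered "
      f"({-rec[0]:.2f}, {-rec[1]:.2f}) px")

# plant a 10-degree rotation about the image center
center = (np.asarray(img.shape) - 1) / 2 * np.asarray(img.spacing)
rot = AffineTransform.from_params(0, 0, np.deg2rad(10.0), center=center)
a = affine_register(img, warp(img, field_from_affine(rot, img)))
ang = np.degrees(np.arctan2(a.linear[1, 0], a.linear[0, 0]))
print(f"planted rotation 10.0 deg -> recovered {abs(ang):.2f} deg")

# plant the case's own smooth random field (max 8 px) and run Demons
fixed = warp(img, case.true_field)
est = demons_register(fixed, img)
epe = endpoint_error(est, case.true_field, case.anatomy_ct.labels > 0)
print(f"Demons mean endpoint error inside the anatomy: {epe:.2f} px "
      f"(planted field max {case.true_field.magnitude().max():.0f} px)")
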