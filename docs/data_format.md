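# Dataset directory format

Both the synthetic generator and the loaders use one layout:

```
<root>/
  images/           RGB fundus images, PNG or JPEG; the file stem is the image id
  masks/            optional; one 8-bit grayscale PNG per image id
  fovea.csv         optional; columns: image_id,fovea_x,fovea_y
  labels.csv        optional; columns: image_id,glaucoma   (0 or 1)
```

Conventions:

* Coordinates are 0-based pixels in the ORIGINAL image frame;
  `fovea_x` is the column, `fovea_y` the row; fractional values are
  allowed. The loader rescales them to the model's input size.
* Masks use the tri-level gray convention: `0` = optic cup (which is
  also disc), `128` = disc outside the cup, `255` = background. The
  decoder accepts any gray value (<= 64 reads as cup, <= 192 as disc)
  so resampled or re-encoded masks still load; pass a strict encoding
  to insist on the exact levels.
* Items may miss any of masks / fovea / label; they are flagged per
  task and simply do not contribute to that task's training or metrics.

## Converting REFUGE annotations

The REFUGE challenge distributes per-image disc/cup segmentation
images, an Excel sheet `Fovea_location(s).xlsx` with columns
`ImgName`, `Fovea_X`, `Fovea_Y`, and a glaucoma label list (or encodes
the label in the directory name, `Glaucoma`/`Non-Glaucoma`). To use
such data here:

1. Copy or link the fundus images into `images/` (the stem becomes the
   image id; strip extensions in the annotation sheets accordingly).
2. Copy the provided segmentation PNGs into `masks/<id>.png`. REFUGE
   masks already follow the tri-level convention above.
3. Export the fovea sheet to CSV with header
   `image_id,fovea_x,fovea_y` (REFUGE coordinates are already pixels in
   the original frame; keep them unscaled).
4. Write `labels.csv` with header `image_id,glaucoma`, with 1 for every
   image in the glaucoma folder or marked positive in the ground-truth
   list, 0 otherwise.

No resizing is needed on disk; resizing and coordinate rescaling happen
at load time.
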