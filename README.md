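# figdig

Recover numeric data from raster images of scientific figures.

Published results — clinical time series, survival curves, scatter plots —
are often available only as figures. Systems-biology model calibration,
systematic reviews and meta-analyses all need the underlying numbers.
`figdig` digitizes such figures: you calibrate the coordinate system by
clicking two points on each axis and typing their values, and every
further click is converted to data coordinates. Because the conversion
decomposes clicks over the axis direction vectors rather than the image
grid, rotated and linearly skewed figures (the usual product of scanning
or photocopying a printed page) digitize correctly with no prior
rectification.

## The method

Four calibration pixels p₁, p₂ (y-axis, values y₂, y₁) and p₃, p₄
(x-axis, values x₁, x₂) define axis vectors

```
a = p₁ − p₂,   b = p₄ − p₃.
```

A further clicked pixel p₅ is decomposed over these vectors by
intersecting lines through p₅ parallel to each axis, giving fractional
positions along the calibrated spans

```
ka = [(p₅₁−p₂₁)b₂ − (p₅₂−p₂₂)b₁] / (a₁b₂ − a₂b₁)
kb = [(p₅₁−p₃₁)a₂ − (p₅₂−p₃₂)a₁] / (a₂b₁ − a₁b₂)
```

and data coordinates

```
x = x₁ + kb(x₂ − x₁)
y = y₁ + ka(y₂ − y₁)          (linear y-axis)
y = y₁ (y₂/y₁)^ka             (logarithmic y-axis, y₁, y₂ > 0)
```

A solution exists iff the axes are linearly independent
(a₁b₂ ≠ a₂b₁); orthogonality is **not** required, which is what buys
tolerance to rotation and shear. The clicking error — the change in data
units caused by selecting a neighbouring pixel — is

```
x_err = |x₁ − x₂| / ‖b‖,   y_err = |y₁ − y₂| / ‖a‖
```

(`y_err` is undefined for a logarithmic y-axis).

## Worked example

A chart with y-axis 0–9 over 300 px and x-axis 0–18 over 400 px, sharing
the origin pixel. Click file (`#` comments allowed; the first four pairs
are the axis intercepts p₁–p₄, then one pair per data point):

```
# p1 p2 p3 p4, then data clicks
100 100
100 400
100 400
500 400
100 300
300 250
```

```sh
$ figdig batch clicks.txt --axes 9 0 0 18 --digits 3 --errors --quiet
[0.000 3.000; 9.000 4.500]
# x_err = 0.045
# y_err = 0.03
```

The two data clicks land at (0, 3) and (9, 4.5): the pixel (100, 300) is
two thirds of the way up a y-axis spanning 0–9, and (300, 250) is the
midpoint of both axes. The error lines say that being one pixel off moves
the result by at most 0.045 x-units and 0.03 y-units — the spans cover
400 and 300 px, so one pixel is 18/400 and 9/300 axis units.

The same numbers come from the library:

```python
>>> import figdig as fd
>>> cal = fd.AxisCalibration(fd.PixelPoint(100, 100), fd.PixelPoint(100, 400),
...                          fd.PixelPoint(100, 400), fd.PixelPoint(500, 400),
...                          y2=9, y1=0, x1=0, x2=18)
>>> cs = fd.build_coordinate_system(cal)
>>> fd.pixel_to_data(cs, (300, 250))
DataPoint(x=9.0, y=4.5)
```

Other entry points: `figdig interactive IMAGE` captures clicks on a
displayed image (keys: `r` reset axes, `n` new data set, `u` undo, `q`
finish), and `figdig fixture --scenario rotated_skewed` generates a
synthetic ground-truth chart (PNG, truth sidecar and simulated clicks
file) for benchmarking. `--style {matlab,r,csv}` selects the output
dialect; omitting `--axes` emits raw pixel coordinates so you can apply
your own transform.

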