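# mlcopt dose plane: mm coordinates, isocenter at (0,0), leaf motion along x,
# y increasing upward; origin is the centre of the top-left pixel,
# top row = largest y.
rows 3
cols 4
spacing_x_mm 2.5
spacing_y_mm 2.5
origin_x_mm -3.75
origin_y_mm 2.5
units cGy
10 20 30 40
50 60 70 80
90 100 110 120
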