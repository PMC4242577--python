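taxon,flowers_per_stem,flower_shape,hypanthium_hair,pollen_color,upper_leaf_shape,upper_leaf_margin,seed_wings,seed_shape_long,seed_cross_section,seed_surface,lower_leaf_shape,lower_leaf_margin
aurita,5,Rotate-subrotate,Glabrous,Purplish,Narrow-elliptic,Inconspicuous-serrate,Periphery ridge,Oblong,Narrowly ovate,Interrupted-striate,Oblanceolate,Inconspicuous-serrate
lasiocarpa,2,Tubular-campanulate,Villous,Purple,Narrow-elliptic,Mucronate,No ridge,Fusiform-ovate,Terete,Striate,Oblanceolate,Mucronate
idahoensis,2,Tubular-campanulate,Hirtellous,White-yellow,Narrow-elliptic,Inconspicuous-serrate,One sided ridge,Oblong,Terete,Striate,Oblanceolate,Inconspicuous-serrate
parryi,2,Broadly campanulate,Glabrous,Yellow,Narrow-elliptic,Sparse-serrate,Opposite hilum,Elliptical,Terete,Striate,Oblanceolate,Sparse-serrate
piperi,3,Rotate-subrotate,Hirtellous,Purple,Narrow-elliptic,Mucronate,Ridge on hilum end,Narrowly elliptical,Terete,Striate,Oblanceolate,Mucronate
scabrella,3,Broadly campanulate,Hirtellous,Purple,Narrow-elliptic,Entire,One sided ridge,Oblong,Ovate,Striate,Oblanceolate,Entire
scouleri,3,Rotate-subrotate,Chaffy,Yellow,Ovate,Conspicuous-serrate,No ridge,Elliptical,Terete,Striate,Oblanceolate,Conspicuous-serrate
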