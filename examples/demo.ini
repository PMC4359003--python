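# Demo-scale end-to-end pipeline configuration.
# Run:  shipworm all --config examples/demo.ini --outdir out/demo

[grid]
n_lat = 10
n_lon = 16
depth_edges = 0 9 12 25 60 100 150
bbox = 10 22 54 58

[scenario]
salinity_west = 32
salinity_east = 3
sst_mean = 9
sst_amplitude = 8
sst_peak_day = 210
warming_trend = 0
halocline_depth = 60
surface_oxygen = 9
bottom_oxygen = 3
gyre_strength = 10000
seed = 0

[hydro]
years = 2000
time_step_days = 1

[envelope]
layers = surface bottom
period = 2000-2000
raster_format = geotiff

[dispersal]
particles_per_cell = 8
releases_per_year = 2
release_months = 6 7
years = 2000
duration_days = 30
substep_minutes = 180

[areas]
west_release = 11.0 55.0  13.5 55.0  13.5 56.5  11.0 56.5
east_reference = 17.0 55.0  19.5 55.0  19.5 56.5  17.0 56.5

[validation]
records = examples/occurrence_synthetic.csv
threshold = 60
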