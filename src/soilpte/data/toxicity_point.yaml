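# Toxicity table for the deterministic (point) risk engine.
#
# rfd: chronic reference doses (mg kg^-1 day^-1) per exposure route;
# sf: carcinogenic slope factors ((mg kg^-1 day^-1)^-1); abs: dermal
# absorption fraction.  Values are the ones conventionally used for these
# elements in the soil health-risk literature (IRIS/PPRTV/CalEPA lineage).
# Elements without a slope factor for a route are excluded from the cancer
# sum for that route.  Carcinogenic risk is evaluated over the ingestion and
# inhalation routes; dermal slope factors are not defaulted because
# gastrointestinal-absorption extrapolation is unavailable for most of
# these elements.

cr_pathways: [ingestion, inhalation]

elements:
  Hg:
    abs: 0.001
    rfd: {ingestion: 3.0e-4, dermal: 2.1e-5, inhalation: 8.57e-5}
  As:
    abs: 0.03
    rfd: {ingestion: 3.0e-4, dermal: 1.23e-4, inhalation: 3.0e-4}
    sf: {ingestion: 1.5, inhalation: 15.1}
  Zn:
    abs: 0.001
    rfd: {ingestion: 0.3, dermal: 0.06, inhalation: 0.3}
  Pb:
    abs: 0.001
    rfd: {ingestion: 3.5e-3, dermal: 5.25e-4, inhalation: 3.52e-3}
    sf: {ingestion: 8.5e-3}
  Co:
    abs: 0.001
    rfd: {ingestion: 2.0e-2, dermal: 1.6e-2, inhalation: 5.71e-6}
    sf: {ingestion: 9.8, inhalation: 9.8}
  Cd:
    abs: 0.001
    rfd: {ingestion: 1.0e-3, dermal: 1.0e-5, inhalation: 1.0e-3}
    sf: {inhalation: 6.3}
  Ni:
    abs: 0.001
    rfd: {ingestion: 2.0e-2, dermal: 5.4e-3, inhalation: 2.06e-2}
    sf: {ingestion: 1.7, inhalation: 0.84}
  Cr:
    abs: 0.001
    rfd: {ingestion: 3.0e-3, dermal: 6.0e-5, inhalation: 2.86e-5}
    sf: {ingestion: 0.5, inhalation: 42.0}
  Cu:
    abs: 0.001
    rfd: {ingestion: 4.0e-2, dermal: 1.2e-2, inhalation: 4.02e-2}
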