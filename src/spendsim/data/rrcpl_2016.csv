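vintage,region,price_category,index,detail_flag
2016,London,food_nonalcoholic,102.2,detailed
2016,London,alcohol_tobacco,103.0,detailed
2016,London,restaurants_hotels,113.0,detailed
2016,Scotland,food_nonalcoholic,99.8,detailed
2016,Scotland,alcohol_tobacco,99.4,detailed
2016,Scotland,restaurants_hotels,100.4,detailed
2016,Wales,food_nonalcoholic,100.8,detailed
2016,Wales,alcohol_tobacco,102.3,detailed
2016,Wales,restaurants_hotels,95.1,detailed
2016,Northern Ireland,food_nonalcoholic,99.7,detailed
2016,Northern Ireland,alcohol_tobacco,98.6,detailed
2016,Northern Ireland,restaurants_hotels,98.3,detailed
2016,South East,food_nonalcoholic,101.5,aggregate
2016,South East,alcohol_tobacco,101.5,aggregate
2016,South East,restaurants_hotels,101.5,aggregate
2016,Eastern,food_nonalcoholic,99.8,aggregate
2016,Eastern,alcohol_tobacco,99.8,aggregate
2016,Eastern,restaurants_hotels,99.8,aggregate
2016,West Midlands,food_nonalcoholic,98.5,aggregate
2016,West Midlands,alcohol_tobacco,98.5,aggregate
2016,West Midlands,restaurants_hotels,98.5,aggregate
2016,South West,food_nonalcoholic,102.4,aggregate
2016,South West,alcohol_tobacco,102.4,aggregate
2016,South West,restaurants_hotels,102.4,aggregate
2016,East Midlands,food_nonalcoholic,99.6,aggregate
2016,East Midlands,alcohol_tobacco,99.6,aggregate
2016,East Midlands,restaurants_hotels,99.6,aggregate
2016,North West,food_nonalcoholic,98.8,aggregate
2016,North West,alcohol_tobacco,98.8,aggregate
2016,North West,restaurants_hotels,98.8,aggregate
2016,North East,food_nonalcoholic,98.8,aggregate
2016,North East,alcohol_tobacco,98.8,aggregate
2016,North East,restaurants_hotels,98.8,aggregate
2016,Yorkshire,food_nonalcoholic,97.7,aggregate
2016,Yorkshire,alcohol_tobacco,97.7,aggregate
2016,Yorkshire,restaurants_hotels,97.7,aggregate
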