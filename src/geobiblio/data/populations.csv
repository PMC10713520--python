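country,population,year
USA,328239523,2019
UK,66834405,2019
Canada,37589262,2019
France,67059887,2019
Germany,83092962,2019
Netherlands,17344874,2019
Australia,25365745,2019
China,1397715000,2019
Switzerland,8575280,2019
Sweden,10278887,2019
Denmark,5818553,2019
Italy,59729081,2019
Japan,126264931,2019
Spain,47134837,2019
Belgium,11488980,2019
Norway,5347896,2019
South Africa,58558270,2019
New Zealand,4979200,2019
Israel,9054000,2019
Brazil,211049527,2019
Finland,5521606,2019
Austria,8879920,2019
South Korea,51709098,2019
India,1366417754,2019
Singapore,5703569,2019
Ireland,4934340,2019
Thailand,69625582,2019
Kenya,52573973,2019
Greece,10721582,2019
Pakistan,216565318,2019
Saudi Arabia,34268528,2019
Bangladesh,163046161,2019
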