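city,country,lat,lng,pop,capital
Washington,USA,38.91,-77.04,705000,1
New York,USA,40.71,-74.01,8336000,0
Boston,USA,42.36,-71.06,692000,0
Los Angeles,USA,34.05,-118.24,3979000,0
Chicago,USA,41.88,-87.63,2693000,0
Houston,USA,29.76,-95.37,2320000,0
Philadelphia,USA,39.95,-75.17,1584000,0
Seattle,USA,47.61,-122.33,753000,0
Baltimore,USA,39.29,-76.61,593000,0
San Francisco,USA,37.77,-122.42,881000,0
Stanford,USA,37.43,-122.17,13800,0
Ann Arbor,USA,42.28,-83.74,120000,0
Durham,USA,35.99,-78.9,278000,0
Atlanta,USA,33.75,-84.39,506000,0
Rochester,USA,44.02,-92.47,118000,0
Bethesda,USA,38.98,-77.1,63000,0
London,UK,51.51,-0.13,8982000,1
Oxford,UK,51.75,-1.26,152000,0
Cambridge,UK,52.21,0.12,124000,0
Edinburgh,UK,55.95,-3.19,524000,0
Manchester,UK,53.48,-2.24,547000,0
Birmingham,UK,52.49,-1.89,1141000,0
Glasgow,UK,55.86,-4.25,633000,0
Bristol,UK,51.45,-2.59,463000,0
Leeds,UK,53.8,-1.55,793000,0
Newcastle,UK,54.98,-1.61,300000,0
Ottawa,Canada,45.42,-75.7,994000,1
Toronto,Canada,43.65,-79.38,2930000,0
Montreal,Canada,45.5,-73.57,1780000,0
Vancouver,Canada,49.28,-123.12,675000,0
Hamilton,Canada,43.26,-79.87,579000,0
London,Canada,42.98,-81.25,404000,0
Calgary,Canada,51.05,-114.07,1336000,0
Edmonton,Canada,53.55,-113.49,981000,0
Paris,France,48.86,2.35,2161000,1
Lyon,France,45.76,4.84,516000,0
Marseille,France,43.3,5.37,870000,0
Toulouse,France,43.6,1.44,493000,0
Bordeaux,France,44.84,-0.58,257000,0
Lille,France,50.63,3.06,233000,0
Berlin,Germany,52.52,13.4,3645000,1
Munich,Germany,48.14,11.58,1472000,0
Hamburg,Germany,53.55,9.99,1841000,0
Heidelberg,Germany,49.4,8.67,160000,0
Frankfurt,Germany,50.11,8.68,753000,0
Cologne,Germany,50.94,6.96,1086000,0
Tubingen,Germany,48.52,9.06,91000,0
Amsterdam,Netherlands,52.37,4.9,873000,1
Rotterdam,Netherlands,51.92,4.48,651000,0
Utrecht,Netherlands,52.09,5.12,358000,0
Leiden,Netherlands,52.16,4.49,125000,0
Groningen,Netherlands,53.22,6.57,233000,0
Nijmegen,Netherlands,51.84,5.85,177000,0
Canberra,Australia,-35.28,149.13,431000,1
Sydney,Australia,-33.87,151.21,5312000,0
Melbourne,Australia,-37.81,144.96,5078000,0
Brisbane,Australia,-27.47,153.03,2560000,0
Perth,Australia,-31.95,115.86,2059000,0
Adelaide,Australia,-34.93,138.6,1345000,0
Beijing,China,39.9,116.41,21540000,1
Shanghai,China,31.23,121.47,24280000,0
Guangzhou,China,23.13,113.26,14900000,0
Wuhan,China,30.59,114.31,11080000,0
Hong Kong,China,22.32,114.17,7482000,0
Chengdu,China,30.57,104.07,16330000,0
Bern,Switzerland,46.95,7.45,134000,1
Zurich,Switzerland,47.38,8.54,415000,0
Geneva,Switzerland,46.2,6.14,201000,0
Basel,Switzerland,47.56,7.59,178000,0
Lausanne,Switzerland,46.52,6.63,140000,0
Stockholm,Sweden,59.33,18.07,975000,1
Gothenburg,Sweden,57.71,11.97,579000,0
Uppsala,Sweden,59.86,17.64,178000,0
Lund,Sweden,55.7,13.19,92000,0
Malmo,Sweden,55.6,13.0,344000,0
Copenhagen,Denmark,55.68,12.57,633000,1
Aarhus,Denmark,56.16,10.2,280000,0
Odense,Denmark,55.4,10.4,180000,0
Aalborg,Denmark,57.05,9.92,119000,0
Rome,Italy,41.9,12.5,2873000,1
Milan,Italy,45.46,9.19,1352000,0
Naples,Italy,40.85,14.27,967000,0
Turin,Italy,45.07,7.69,870000,0
Bologna,Italy,44.49,11.34,389000,0
Florence,Italy,43.77,11.26,382000,0
Tokyo,Japan,35.68,139.69,13960000,1
Osaka,Japan,34.69,135.5,2691000,0
Kyoto,Japan,35.01,135.77,1475000,0
Yokohama,Japan,35.44,139.64,3749000,0
Nagoya,Japan,35.18,136.91,2296000,0
Madrid,Spain,40.42,-3.7,3223000,1
Barcelona,Spain,41.39,2.17,1620000,0
Valencia,Spain,39.47,-0.38,791000,0
Seville,Spain,37.39,-5.99,688000,0
Brussels,Belgium,50.85,4.35,1209000,1
Antwerp,Belgium,51.22,4.4,523000,0
Ghent,Belgium,51.05,3.72,262000,0
Leuven,Belgium,50.88,4.7,101000,0
Oslo,Norway,59.91,10.75,681000,1
Bergen,Norway,60.39,5.32,283000,0
Trondheim,Norway,63.43,10.4,205000,0
Pretoria,South Africa,-25.75,28.19,741000,1
Cape Town,South Africa,-33.92,18.42,433000,0
Johannesburg,South Africa,-26.2,28.05,957000,0
Durban,South Africa,-29.86,31.03,595000,0
Wellington,New Zealand,-41.29,174.78,212000,1
Auckland,New Zealand,-36.85,174.76,1657000,0
Christchurch,New Zealand,-43.53,172.64,381000,0
Dunedin,New Zealand,-45.87,170.5,126000,0
Jerusalem,Israel,31.77,35.21,936000,1
Tel Aviv,Israel,32.09,34.78,460000,0
Haifa,Israel,32.79,34.99,285000,0
Rehovot,Israel,31.89,34.81,143000,0
Brasilia,Brazil,-15.79,-47.88,3055000,1
Sao Paulo,Brazil,-23.55,-46.63,12330000,0
Rio de Janeiro,Brazil,-22.91,-43.17,6748000,0
Salvador,Brazil,-12.97,-38.5,2886000,0
Helsinki,Finland,60.17,24.94,656000,1
Turku,Finland,60.45,22.27,193000,0
Tampere,Finland,61.5,23.76,238000,0
Oulu,Finland,65.01,25.47,205000,0
Vienna,Austria,48.21,16.37,1897000,1
Graz,Austria,47.07,15.44,291000,0
Innsbruck,Austria,47.27,11.4,132000,0
Salzburg,Austria,47.81,13.06,155000,0
Seoul,South Korea,37.57,126.98,9776000,1
Busan,South Korea,35.18,129.08,3449000,0
Daegu,South Korea,35.87,128.6,2466000,0
Incheon,South Korea,37.46,126.71,2957000,0
New Delhi,India,28.61,77.21,257000,1
Mumbai,India,19.08,72.88,12440000,0
Bangalore,India,12.97,77.59,8443000,0
Chennai,India,13.08,80.27,7090000,0
Vellore,India,12.92,79.13,185000,0
Singapore,Singapore,1.35,103.82,5704000,1
Dublin,Ireland,53.35,-6.26,554000,1
Cork,Ireland,51.9,-8.47,125000,0
Galway,Ireland,53.27,-9.06,80000,0
Bangkok,Thailand,13.76,100.5,8281000,1
Chiang Mai,Thailand,18.79,98.98,127000,0
Khon Kaen,Thailand,16.44,102.84,115000,0
Nairobi,Kenya,-1.29,36.82,4397000,1
Mombasa,Kenya,-4.04,39.67,1208000,0
Kisumu,Kenya,-0.09,34.77,397000,0
Athens,Greece,37.98,23.73,664000,1
Thessaloniki,Greece,40.64,22.94,315000,0
Patras,Greece,38.25,21.73,168000,0
Islamabad,Pakistan,33.69,73.04,1015000,1
Karachi,Pakistan,24.86,67.01,14910000,0
Lahore,Pakistan,31.55,74.34,11130000,0
Riyadh,Saudi Arabia,24.71,46.68,7676000,1
Jeddah,Saudi Arabia,21.49,39.19,4697000,0
Dammam,Saudi Arabia,26.43,50.1,1253000,0
Dhaka,Bangladesh,23.81,90.41,8906000,1
Chittagong,Bangladesh,22.36,91.78,2581000,0
Sylhet,Bangladesh,24.89,91.87,526000,0
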